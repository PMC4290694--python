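"""Run configuration: YAML schema, validation and defaults.

A run config either simulates a dataset (``simulate:`` section) or loads one
from disk (``data:`` section with expression/phenotype/network paths), then
runs every requested (method, classifier) pair on one shared fold plan.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import yaml

from .classifiers import CLASSIFIER_KINDS
from .errors import ConfigError
from .feature_selection import METHODS
from .synthetic_data import SimulationConfig


@dataclass
class RunConfig:
    methods: tuple = tuple(METHODS)
    classifiers: tuple = ("dlda",)
    k: int = 5
    rounds: int = 100
    n_features: dict = field(default_factory=dict)  # method -> int; default below
    n_features_default: int = 50
    min_degree: int = 5
    netrank_a: float = 0.3
    netrank_tol: float = 1e-9
    netrank_max_iter: int = 1000
    seed: int = 0
    stratified: bool = True
    easy_threshold: float = 0.95
    hard_threshold: float = 0.05
    heatmap: bool = False
    out_dir: str = "progsig_run"
    simulate: SimulationConfig | None = None
    data: dict | None = None  # expression / phenotype / network paths

    def features_for(self, method: str) -> int:
        return int(self.n_features.get(method, self.n_features_default))

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["methods"] = list(self.methods)
        d["classifiers"] = list(self.classifiers)
        return d


_TOP_KEYS = {
    "methods",
    "classifiers",
    "k",
    "rounds",
    "n_features",
    "min_degree",
    "netrank",
    "seed",
    "stratified",
    "easy_threshold",
    "hard_threshold",
    "heatmap",
    "out_dir",
    "simulate",
    "data",
}
_NETRANK_KEYS = {"a", "tol", "max_iter"}
_DATA_KEYS = {"expression", "phenotype", "network"}
_SIM_KEYS = {f.name for f in dataclasses.fields(SimulationConfig)}


def config_from_dict(raw: dict) -> RunConfig:
    """Validate a parsed YAML mapping, collecting *all* violations."""
    problems = []
    if not isinstance(raw, dict):
        raise ConfigError(["config root must be a mapping"])
    unknown = sorted(set(raw) - _TOP_KEYS)
    for key in unknown:
        problems.append(f"unknown key {key!r}")

    cfg = RunConfig()

    methods = raw.get("methods", list(METHODS))
    if not isinstance(methods, (list, tuple)) or not methods:
        problems.append("methods must be a non-empty list")
    else:
        for m in methods:
            if m not in METHODS:
                problems.append(f"unknown method {m!r}; roster is {list(METHODS)}")
        cfg.methods = tuple(methods)

    classifiers = raw.get("classifiers", ["dlda"])
    if not isinstance(classifiers, (list, tuple)) or not classifiers:
        problems.append("classifiers must be a non-empty list")
    else:
        for c in classifiers:
            if c not in CLASSIFIER_KINDS:
                problems.append(f"unknown classifier {c!r}; roster is {list(CLASSIFIER_KINDS)}")
        cfg.classifiers = tuple(classifiers)

    for key, attr, cast, check, msg in [
        ("k", "k", int, lambda v: v >= 2, "k must be an integer >= 2"),
        ("rounds", "rounds", int, lambda v: v >= 1, "rounds must be a positive integer"),
        ("min_degree", "min_degree", int, lambda v: v >= 1, "min_degree must be >= 1"),
        ("seed", "seed", int, lambda v: True, "seed must be an integer"),
    ]:
        if key in raw:
            try:
                v = cast(raw[key])
                if not check(v):
                    raise ValueError
                setattr(cfg, attr, v)
            except (TypeError, ValueError):
                problems.append(msg)

    nf = raw.get("n_features", 50)
    if isinstance(nf, dict):
        for m, v in nf.items():
            if m not in METHODS:
                problems.append(f"n_features: unknown method {m!r}")
            elif not isinstance(v, int) or v < 1:
                problems.append(f"n_features[{m!r}] must be a positive integer")
        cfg.n_features = {m: v for m, v in nf.items() if m in METHODS}
    elif isinstance(nf, int) and nf >= 1:
        cfg.n_features_default = nf
    else:
        problems.append("n_features must be a positive integer or a method->int mapping")

    nr = raw.get("netrank", {})
    if not isinstance(nr, dict):
        problems.append("netrank must be a mapping with keys a / tol / max_iter")
    else:
        for key in sorted(set(nr) - _NETRANK_KEYS):
            problems.append(f"netrank: unknown key {key!r}")
        if "a" in nr:
            try:
                a = float(nr["a"])
                if not (0.0 <= a < 1.0):
                    raise ValueError
                cfg.netrank_a = a
            except (TypeError, ValueError):
                problems.append("netrank.a must be in [0,1)")
        if "tol" in nr:
            try:
                tol = float(nr["tol"])
                if tol <= 0:
                    raise ValueError
                cfg.netrank_tol = tol
            except (TypeError, ValueError):
                problems.append("netrank.tol must be a positive number")
        if "max_iter" in nr:
            try:
                mi = int(nr["max_iter"])
                if mi < 1:
                    raise ValueError
                cfg.netrank_max_iter = mi
            except (TypeError, ValueError):
                problems.append("netrank.max_iter must be a positive integer")

    for key, lo, hi in [("easy_threshold", 0.0, 1.0), ("hard_threshold", 0.0, 1.0)]:
        if key in raw:
            try:
                v = float(raw[key])
                if not (lo <= v <= hi):
                    raise ValueError
                setattr(cfg, key, v)
            except (TypeError, ValueError):
                problems.append(f"{key} must be a number in [0,1]")

    for key in ("stratified", "heatmap"):
        if key in raw:
            if not isinstance(raw[key], bool):
                problems.append(f"{key} must be a boolean")
            else:
                setattr(cfg, key, raw[key])
    if "out_dir" in raw:
        cfg.out_dir = str(raw["out_dir"])

    sim = raw.get("simulate")
    data = raw.get("data")
    if sim is not None and data is not None:
        problems.append("give either 'simulate' or 'data', not both")
    if sim is None and data is None:
        sim = {}  # default simulation
    if sim is not None:
        if not isinstance(sim, dict):
            problems.append("simulate must be a mapping of SimulationConfig fields")
        else:
            for key in sorted(set(sim) - _SIM_KEYS):
                problems.append(f"simulate: unknown key {key!r} (fields: {sorted(_SIM_KEYS)})")
            try:
                sim_cfg = SimulationConfig(**{k: v for k, v in sim.items() if k in _SIM_KEYS})
                if "seed" not in sim:
                    sim_cfg.seed = cfg.seed
                sim_cfg.validate()
                cfg.simulate = sim_cfg
            except ConfigError as exc:
                problems.extend(f"simulate: {v}" for v in exc.violations)
            except (TypeError, ValueError) as exc:
                problems.append(f"simulate: {exc}")
    if data is not None:
        if not isinstance(data, dict):
            problems.append("data must be a mapping with expression/phenotype/network paths")
        else:
            for key in sorted(set(data) - _DATA_KEYS):
                problems.append(f"data: unknown key {key!r}")
            for key in ("expression", "phenotype"):
                if key not in data:
                    problems.append(f"data.{key} path is required")
            cfg.data = {k: str(v) for k, v in data.items() if k in _DATA_KEYS}

    if problems:
        raise ConfigError(problems)
    return cfg


def validate_config(path) -> RunConfig:
    """Parse and validate a YAML run config, reporting all violations at once."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if raw is None:
        raw = {}
    return config_from_dict(raw)
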