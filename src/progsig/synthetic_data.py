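"""Synthetic two-class expression datasets with planted, ground-truth signal.

Three signal archetypes can be planted on top of an i.i.d. Gaussian
log-expression baseline:

* *DE genes* - a mean shift of ``de_effect`` (in units of the noise SD) in the
  PP class;
* *DE gene-sets* - the same shift applied to every member of a chosen hub's
  gene-set;
* *correlation-flip hubs* - interactor profiles generated conditionally on the
  hub profile with class-specific correlation (``rho_gp`` vs ``rho_pp``).

Survival times are drawn from disjoint class-specific uniform distributions so
that good-prognosis samples always outlive poor-prognosis samples.
"""

from __future__ import annotations

import dataclasses
import json
import os
from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigError
from .io_data import (
    AlignedDataset,
    ExpressionMatrix,
    PhenotypeTable,
    align,
    read_expression,
    read_phenotype,
    write_expression,
    write_phenotype,
)
from .network import PPINetwork, read_edge_list, write_edge_list


@dataclass
class SimulationConfig:
    n_genes: int = 2000
    n_gp: int = 25
    n_pp: int = 22
    # network
    n_hubs: int = 50
    hub_degree_min: int = 5
    hub_degree_max: int = 8
    n_background_edges: int = 1500
    # planted signal
    n_de_genes: int = 20
    de_effect: float = 2.0
    n_de_sets: int = 5
    de_set_effect: float = 1.5
    n_flip_hubs: int = 5
    rho_gp: float = 0.8
    rho_pp: float = -0.8
    # survival (years); GP strictly above PP by default
    surv_gp: tuple = (4.0, 10.0)
    surv_pp: tuple = (0.1, 1.0)
    noise_sd: float = 1.0
    t_noise_df: float | None = None  # heavier-tailed baseline behind a flag
    seed: int = 0

    def validate(self):
        problems = []
        if self.n_hubs * self.hub_degree_max > self.n_genes - self.n_hubs:
            problems.append("not enough genes for the requested hubs and interactors")
        if not (1 <= self.hub_degree_min <= self.hub_degree_max):
            problems.append("hub degree range invalid")
        if self.n_de_sets + self.n_flip_hubs > self.n_hubs:
            problems.append("n_de_sets + n_flip_hubs exceeds n_hubs (plants must be disjoint)")
        for rho in (self.rho_gp, self.rho_pp):
            if not (-1.0 < rho < 1.0):
                problems.append(f"|rho| must be < 1, got {rho}")
        if self.de_effect < 0 or self.de_set_effect < 0:
            problems.append("effect sizes must be non-negative")
        if self.noise_sd <= 0:
            problems.append("noise_sd must be positive")
        if problems:
            raise ConfigError(problems)


@dataclass
class GroundTruth:
    de_genes: tuple = ()
    de_sets: tuple = ()       # hub ids of the shifted gene-sets
    flip_hubs: tuple = ()
    extra: dict = field(default_factory=dict)

    def to_dict(self):
        return {
            "de_genes": list(self.de_genes),
            "de_sets": list(self.de_sets),
            "flip_hubs": list(self.flip_hubs),
            **self.extra,
        }


def _gene_ids(n):
    width = max(4, len(str(n - 1)))
    return [f"G{i:0{width}d}" for i in range(n)]


def simulate_network(cfg: SimulationConfig) -> PPINetwork:
    """Star cores for exactly ``n_hubs`` hubs plus degree-capped background edges.

    Hub interactor sets are disjoint and background edges never raise a
    non-hub gene's degree to the hub threshold (5), so ``find_hubs`` returns
    exactly the planted hubs.
    """
    cfg.validate()
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 1]))
    genes = _gene_ids(cfg.n_genes)
    pool = list(rng.permutation(genes))
    hubs = [pool.pop() for _ in range(cfg.n_hubs)]
    edges = []
    for h in hubs:
        d = int(rng.integers(cfg.hub_degree_min, cfg.hub_degree_max + 1))
        for _ in range(d):
            edges.append((h, pool.pop()))
    # background edges among the remaining non-hub genes, degree capped at 4
    degree = {}
    rest = pool
    attempts = 0
    n_added = 0
    existing = set()
    while n_added < cfg.n_background_edges and attempts < 50 * cfg.n_background_edges:
        attempts += 1
        i, j = rng.integers(0, len(rest), size=2)
        if i == j:
            continue
        u, v = rest[i], rest[j]
        key = (u, v) if u < v else (v, u)
        if key in existing:
            continue
        if degree.get(u, 0) >= 4 or degree.get(v, 0) >= 4:
            continue
        existing.add(key)
        degree[u] = degree.get(u, 0) + 1
        degree[v] = degree.get(v, 0) + 1
        edges.append(key)
        n_added += 1
    return PPINetwork(edges)


def simulate_expression(net: PPINetwork, cfg: SimulationConfig):
    """Expression, phenotype and ground truth on top of a simulated network."""
    cfg.validate()
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 2]))
    genes = _gene_ids(cfg.n_genes)
    n = cfg.n_gp + cfg.n_pp
    sigma = cfg.noise_sd
    if cfg.t_noise_df:
        values = sigma * rng.standard_t(cfg.t_noise_df, size=(cfg.n_genes, n))
    else:
        values = rng.normal(0.0, sigma, size=(cfg.n_genes, n))
    gp_cols = np.arange(cfg.n_gp)
    pp_cols = np.arange(cfg.n_gp, n)
    gidx = {g: i for i, g in enumerate(genes)}

    from .network import find_hubs  # local import avoids cycle at module load

    hubs = find_hubs(net, cfg.hub_degree_min)
    hub_order = list(rng.permutation(hubs))
    flip_hubs = sorted(hub_order[: cfg.n_flip_hubs])
    de_set_hubs = sorted(hub_order[cfg.n_flip_hubs : cfg.n_flip_hubs + cfg.n_de_sets])
    special = set(flip_hubs) | set(de_set_hubs)
    special_members = set()
    for h in special:
        special_members.update(net.neighbors(h))

    # DE genes live in the network (so netrank can see them) but outside the
    # planted hub structures; fall back to any unplanted gene if necessary
    candidates = [
        g
        for g in net.nodes
        if g not in special and g not in special_members and net.degree(g) < cfg.hub_degree_min
    ]
    if len(candidates) < cfg.n_de_genes:
        candidates = [g for g in genes if g not in special and g not in special_members]
    de_genes = sorted(rng.choice(candidates, size=cfg.n_de_genes, replace=False))

    for g in de_genes:
        values[gidx[g], pp_cols] += cfg.de_effect * sigma
    for h in de_set_hubs:
        for m in (h, *net.neighbors(h)):
            values[gidx[m], pp_cols] += cfg.de_set_effect * sigma
    for h in flip_hubs:
        hub_row = values[gidx[h]]
        for interactor in net.neighbors(h):
            row = np.empty(n)
            for cols, rho in ((gp_cols, cfg.rho_gp), (pp_cols, cfg.rho_pp)):
                noise = rng.normal(0.0, sigma, size=cols.size)
                row[cols] = rho * hub_row[cols] + np.sqrt(1.0 - rho**2) * noise
            values[gidx[interactor]] = row

    sample_ids = [f"GP{i + 1:02d}" for i in range(cfg.n_gp)] + [
        f"PP{i + 1:02d}" for i in range(cfg.n_pp)
    ]
    classes = np.array(["GP"] * cfg.n_gp + ["PP"] * cfg.n_pp, dtype=object)
    survival = np.concatenate(
        [
            rng.uniform(*cfg.surv_gp, size=cfg.n_gp),
            rng.uniform(*cfg.surv_pp, size=cfg.n_pp),
        ]
    )
    expr = ExpressionMatrix(tuple(genes), tuple(sample_ids), values)
    pheno = PhenotypeTable(tuple(sample_ids), classes, survival)
    truth = GroundTruth(
        de_genes=tuple(de_genes), de_sets=tuple(de_set_hubs), flip_hubs=tuple(flip_hubs)
    )
    return expr, pheno, truth


def simulate_dataset(cfg: SimulationConfig):
    """Convenience: network + expression + alignment in one call."""
    net = simulate_network(cfg)
    expr, pheno, truth = simulate_expression(net, cfg)
    return align(expr, pheno, net), truth


# ---------------------------------------------------------------------------
# subspace-specific signal (different methods capture different patients)
# ---------------------------------------------------------------------------

@dataclass
class SubspaceConfig:
    """Plant DE-gene signal in one half of the PP class and correlation-flip
    signal in the other half, so single-gene and differential-correlation
    methods each classify a different patient subspace."""

    n_genes: int = 1000
    n_gp: int = 20
    n_pp: int = 32
    n_hubs: int = 20
    hub_degree_min: int = 5
    hub_degree_max: int = 7
    n_background_edges: int = 500
    n_de_genes: int = 20
    de_effect: float = 4.0
    n_flip_hubs: int = 5
    rho: float = 0.9
    surv_gp: tuple = (4.0, 10.0)
    surv_pp: tuple = (0.1, 1.0)
    noise_sd: float = 1.0
    seed: int = 0


def simulate_subspace_dataset(cfg: SubspaceConfig):
    """Build the split-signal dataset; truth.extra records the PP halves."""
    base = SimulationConfig(
        n_genes=cfg.n_genes,
        n_gp=cfg.n_gp,
        n_pp=cfg.n_pp,
        n_hubs=cfg.n_hubs,
        hub_degree_min=cfg.hub_degree_min,
        hub_degree_max=cfg.hub_degree_max,
        n_background_edges=cfg.n_background_edges,
        n_de_genes=0,
        n_de_sets=0,
        n_flip_hubs=0,
        noise_sd=cfg.noise_sd,
        surv_gp=cfg.surv_gp,
        surv_pp=cfg.surv_pp,
        seed=cfg.seed,
    )
    net = simulate_network(base)
    expr, pheno, _ = simulate_expression(net, base)
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 3]))
    values = expr.values
    genes = list(expr.gene_ids)
    gidx = {g: i for i, g in enumerate(genes)}
    n = cfg.n_gp + cfg.n_pp
    gp_cols = np.arange(cfg.n_gp)
    pp_cols = np.arange(cfg.n_gp, n)
    half = cfg.n_pp // 2
    pp_a = pp_cols[:half]          # DE-gene half
    pp_b = pp_cols[half:]          # correlation-flip half

    from .network import find_hubs

    hubs = find_hubs(net, cfg.hub_degree_min)
    flip_hubs = sorted(rng.permutation(hubs)[: cfg.n_flip_hubs])
    members = set(flip_hubs)
    for h in flip_hubs:
        members.update(net.neighbors(h))
    candidates = [g for g in net.nodes if g not in members and net.degree(g) < cfg.hub_degree_min]
    de_genes = sorted(rng.choice(candidates, size=cfg.n_de_genes, replace=False))

    sigma = cfg.noise_sd
    for g in de_genes:
        values[gidx[g], pp_a] += cfg.de_effect * sigma
    for h in flip_hubs:
        hub_row = values[gidx[h]]
        for interactor in net.neighbors(h):
            row = np.empty(n)
            for cols, rho in (
                (gp_cols, cfg.rho),
                (pp_a, cfg.rho),       # flip only in the B half
                (pp_b, -cfg.rho),
            ):
                noise = rng.normal(0.0, sigma, size=cols.size)
                row[cols] = rho * hub_row[cols] + np.sqrt(1.0 - rho**2) * noise
            values[gidx[interactor]] = row

    truth = GroundTruth(
        de_genes=tuple(de_genes),
        flip_hubs=tuple(flip_hubs),
        extra={
            "pp_de_samples": [expr.sample_ids[i] for i in pp_a],
            "pp_flip_samples": [expr.sample_ids[i] for i in pp_b],
        },
    )
    expr = ExpressionMatrix(expr.gene_ids, expr.sample_ids, values)
    return align(expr, pheno, net), truth


# ---------------------------------------------------------------------------
# on-disk round trip
# ---------------------------------------------------------------------------

def write_dataset(expr, pheno, net, truth, out_dir):
    """Write expression.tsv / phenotype.tsv / network.tsv / truth.json."""
    os.makedirs(out_dir, exist_ok=True)
    write_expression(expr, os.path.join(out_dir, "expression.tsv"))
    write_phenotype(pheno, os.path.join(out_dir, "phenotype.tsv"))
    write_edge_list(net, os.path.join(out_dir, "network.tsv"))
    with open(os.path.join(out_dir, "truth.json"), "w") as fh:
        json.dump(truth.to_dict(), fh, indent=2, sort_keys=True)
        fh.write("\n")
    return out_dir


def read_dataset(in_dir):
    """Load a directory written by :func:`write_dataset`."""
    expr = read_expression(os.path.join(in_dir, "expression.tsv"))
    pheno = read_phenotype(os.path.join(in_dir, "phenotype.tsv"))
    net = read_edge_list(os.path.join(in_dir, "network.tsv"))
    truth_path = os.path.join(in_dir, "truth.json")
    truth = None
    if os.path.exists(truth_path):
        with open(truth_path) as fh:
            d = json.load(fh)
        truth = GroundTruth(
            de_genes=tuple(d.pop("de_genes", ())),
            de_sets=tuple(d.pop("de_sets", ())),
            flip_hubs=tuple(d.pop("flip_hubs", ())),
            extra=d,
        )
    return expr, pheno, net, truth


def config_to_dict(cfg) -> dict:
    return dataclasses.asdict(cfg)
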