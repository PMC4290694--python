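"""Repeated stratified K-fold cross-validation with in-fold feature selection,
and the three evaluation layers: error estimation, feature-selection
stability, and patient-level accuracy.

All feature selection (including the survival correlations used by netrank
and the within-class correlations used by taylor / bss_wss) is computed from
training-fold samples only; test samples never influence the chosen features.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import feature_matrix as fm
from . import feature_selection as fs
from .io_data import AlignedDataset
from .network import DEFAULT_MIN_DEGREE, find_hubs, hub_subnetworks, subnetworks_to_genesets

DEFAULT_TOP_NS = (20, 30, 40, 50)


# ---------------------------------------------------------------------------
# fold plans
# ---------------------------------------------------------------------------

@dataclass
class FoldPlan:
    """R rounds of a K-way partition of the sample indices."""

    K: int
    R: int
    seed: int
    assignment: list  # R lists of K integer index arrays
    n_samples: int

    def __post_init__(self):
        for r, folds in enumerate(self.assignment):
            flat = np.sort(np.concatenate(folds))
            if not np.array_equal(flat, np.arange(self.n_samples)):
                raise ValueError(f"round {r}: folds do not partition the samples")
            sizes = [len(f) for f in folds]
            if max(sizes) - min(sizes) > 1:
                raise ValueError(f"round {r}: fold sizes {sizes} differ by more than 1")

    def __eq__(self, other):
        if not isinstance(other, FoldPlan):
            return NotImplemented
        if (self.K, self.R, self.n_samples) != (other.K, other.R, other.n_samples):
            return False
        return all(
            np.array_equal(a, b)
            for fa, fb in zip(self.assignment, other.assignment)
            for a, b in zip(fa, fb)
        )


def make_fold_plan(labels, K: int = 5, R: int = 100, seed: int = 0, stratified: bool = True) -> FoldPlan:
    """Seeded, per-round regenerated partition into K near-equal folds.

    Stratified by default: each class is dealt round-robin into the folds so
    every fold's class mix approximates the cohort's.  Falls back to
    unstratified (with a warning) when a class is smaller than K.
    """
    labels = np.asarray(labels, dtype=object)
    n = labels.size
    if n < K:
        raise ValueError(f"need at least K={K} samples, got {n}")
    rng = np.random.default_rng(seed)
    class_idx = {k: np.flatnonzero(labels == k) for k in sorted(set(labels))}
    if stratified and any(v.size < K for v in class_idx.values()):
        warnings.warn(
            "a class has fewer samples than K; falling back to unstratified folds",
            stacklevel=2,
        )
        stratified = False
    assignment = []
    for _ in range(R):
        folds = [[] for _ in range(K)]
        if stratified:
            for k in sorted(class_idx):
                members = rng.permutation(class_idx[k])
                base, rem = divmod(members.size, K)
                # folds currently smallest take the remainder, ties shuffled
                order = rng.permutation(K)
                order = sorted(order, key=lambda f: (len(folds[f]), np.flatnonzero(order == f)[0]))
                pos = 0
                for j, f in enumerate(order):
                    take = base + (1 if j < rem else 0)
                    folds[f].extend(members[pos : pos + take])
                    pos += take
        else:
            members = rng.permutation(n)
            base, rem = divmod(n, K)
            pos = 0
            for f in range(K):
                take = base + (1 if f < rem else 0)
                folds[f].extend(members[pos : pos + take])
                pos += take
        assignment.append([np.sort(np.array(f, dtype=int)) for f in folds])
    return FoldPlan(K=K, R=R, seed=seed, assignment=assignment, n_samples=n)


# ---------------------------------------------------------------------------
# the CV engine
# ---------------------------------------------------------------------------

@dataclass
class CVResult:
    method: str
    classifier_kind: str
    sample_ids: tuple
    labels: np.ndarray          # true labels, aligned to sample_ids
    predictions: np.ndarray     # (R, n) object array of predicted labels
    selections: list            # R lists of K tuples of selected feature ids
    plan: FoldPlan
    skipped_folds: list = field(default_factory=list)

    @property
    def R(self):
        return self.plan.R

    def all_selected_lists(self):
        return [sel for round_sel in self.selections for sel in round_sel if sel is not None]


def _selector_state(data: AlignedDataset, method: str, min_degree: int):
    """Label-free structural preparation shared by all folds."""
    if method in ("median_set", "taylor", "bss_wss"):
        hubs = find_hubs(data.network, min_degree)
        subnets = hub_subnetworks(data.network, hubs)
        if method == "median_set":
            return {"genesets": subnetworks_to_genesets(subnets)}
        return {"subnets": subnets}
    return {}


def _select_and_featurize(
    data, method, state, train_idx, n_features, netrank_params
):
    """Rank features on the training columns; return (ids, featurizer)."""
    expr_tr = data.expression.subset_samples_by_index(train_idx)
    y_tr = data.labels[train_idx]
    if method == "mod_t":
        ranked = fs.moderated_t(expr_tr, y_tr)
    elif method == "median_set":
        ranked = fs.median_set_scores(expr_tr, y_tr, state["genesets"])
    elif method == "netrank":
        ranked = fs.netrank(
            expr_tr, data.survival[train_idx], data.network, netrank_params
        )
    elif method == "taylor":
        ranked = fs.taylor_score(expr_tr, y_tr, state["subnets"])
    elif method == "bss_wss":
        ranked = fs.bss_wss_score(expr_tr, y_tr, state["subnets"])
    else:
        raise ValueError(f"unknown method {method!r}; expected one of {fs.METHODS}")
    if len(ranked) == 0:
        return None, None
    top = fs.select_top(ranked, n_features)
    ids = top.feature_ids

    if method in ("mod_t", "netrank"):
        def featurize(expr):
            return fm.gene_features(expr, ids)
    elif method == "median_set":
        chosen = [gs for gs in state["genesets"] if gs.set_id in set(ids)]
        chosen.sort(key=lambda gs: ids.index(gs.set_id))

        def featurize(expr):
            return fm.set_median_features(expr, chosen)
    else:
        chosen = [sn for sn in state["subnets"] if sn.hub in set(ids)]
        chosen.sort(key=lambda sn: ids.index(sn.hub))
        if method == "taylor":
            def featurize(expr):
                return fm.edge_difference_features(expr, chosen)
        else:
            def featurize(expr):
                return fm.hub_gene_features(expr, chosen)
    return ids, featurize


def run_cv(
    data: AlignedDataset,
    method: str,
    classifier,
    plan: FoldPlan,
    n_features: int = 50,
    min_degree: int = DEFAULT_MIN_DEGREE,
    netrank_params: fs.NetRankParams | None = None,
) -> CVResult:
    """Run the full CV loop for one (method, classifier) combination.

    ``classifier`` is any trainer exposing ``train(X, y) -> TrainedClassifier``
    (see :func:`progsig.classifiers.make_trainer`).
    """
    n = data.expression.n_samples
    if plan.n_samples != n:
        raise ValueError("fold plan was built for a different number of samples")
    state = _selector_state(data, method, min_degree)
    predictions = np.full((plan.R, n), None, dtype=object)
    selections = []
    skipped = []
    for r in range(plan.R):
        round_sel = []
        for k, test_idx in enumerate(plan.assignment[r]):
            train_idx = np.setdiff1d(np.arange(n), test_idx)
            ids, featurize = _select_and_featurize(
                data, method, state, train_idx, n_features, netrank_params
            )
            if ids is None:
                warnings.warn(
                    f"round {r} fold {k}: feature selection yielded 0 features; "
                    f"fold skipped",
                    stacklevel=2,
                )
                round_sel.append(None)
                skipped.append((r, k))
                continue
            round_sel.append(ids)
            X_tr = featurize(data.expression.subset_samples_by_index(train_idx))
            X_te = featurize(data.expression.subset_samples_by_index(test_idx))
            trained = classifier.train(X_tr, data.labels[train_idx])
            predictions[r, test_idx] = trained.predict(X_te)
        selections.append(round_sel)
    return CVResult(
        method=method,
        classifier_kind=getattr(classifier, "kind", "unknown"),
        sample_ids=data.expression.sample_ids,
        labels=np.asarray(data.labels, dtype=object),
        predictions=predictions,
        selections=selections,
        plan=plan,
        skipped_folds=skipped,
    )


# ---------------------------------------------------------------------------
# evaluation criteria
# ---------------------------------------------------------------------------

def overall_error(res: CVResult) -> float:
    """Fraction of misclassified predictions over all R x n test predictions.

    With folds covering every sample once per round this equals the average
    over rounds of the per-round test error, and it reconstructs exactly from
    the patient accuracy matrix (1 - mean(counts)/R).
    """
    made = res.predictions != None  # noqa: E711 - elementwise on object array
    if not made.any():
        raise ValueError("no predictions were made")
    wrong = (res.predictions != res.labels[None, :]) & made
    return float(wrong.sum() / made.sum())


def class_specific_error(res: CVResult) -> dict:
    """Error restricted to samples of each class."""
    out = {}
    for k in ("GP", "PP"):
        mask = res.labels == k
        made = res.predictions[:, mask] != None  # noqa: E711
        wrong = (res.predictions[:, mask] != res.labels[None, mask]) & made
        out[k] = float(wrong.sum() / made.sum()) if made.any() else float("nan")
    return out


@dataclass
class PatientAccuracyMatrix:
    """Per sample: number of CV rounds (out of R) with a correct prediction."""

    sample_ids: tuple
    counts: np.ndarray
    R: int

    def fractions(self) -> np.ndarray:
        return self.counts / self.R


def patient_accuracy(res: CVResult) -> PatientAccuracyMatrix:
    correct = (res.predictions == res.labels[None, :]).sum(axis=0)
    return PatientAccuracyMatrix(res.sample_ids, np.asarray(correct, dtype=int), res.R)


def categorize_patients(
    acc: PatientAccuracyMatrix, easy: float = 0.95, hard: float = 0.05
) -> dict:
    """Per-sample category under a single method: easy / hard / differential."""
    frac = acc.fractions()
    out = {}
    for s, f in zip(acc.sample_ids, frac):
        out[s] = "easy" if f >= easy else ("hard" if f <= hard else "differential")
    return out


@dataclass
class StabilityProfile:
    """Mean pairwise top-n overlap of the selected feature lists."""

    method: str
    overlap: dict    # n -> mean pairwise |intersection|
    fraction: dict   # n -> overlap / n
    n_lists: int


def stability(lists, top_ns=DEFAULT_TOP_NS, method: str = "") -> StabilityProfile:
    """Mean over all unordered pairs of lists of |top-n intersection|.

    Computed exactly via per-feature occurrence counts:
    sum_f C(m_f, 2) / C(L, 2), rather than enumerating all pairs.
    """
    lists = [tuple(l) for l in lists if l is not None]
    L = len(lists)
    if L < 2:
        raise ValueError("stability requires at least 2 selected feature lists")
    overlap, fraction = {}, {}
    short = any(len(l) < max(top_ns) for l in lists)
    if short:
        warnings.warn(
            "some selected lists are shorter than the largest top-n; truncating",
            stacklevel=2,
        )
    pairs = L * (L - 1) / 2
    for n in top_ns:
        counts = {}
        for l in lists:
            for f in l[:n]:
                counts[f] = counts.get(f, 0) + 1
        total = sum(m * (m - 1) // 2 for m in counts.values())
        overlap[n] = total / pairs
        fraction[n] = overlap[n] / n
    return StabilityProfile(method=method, overlap=overlap, fraction=fraction, n_lists=L)


# ---------------------------------------------------------------------------
# cross-method report
# ---------------------------------------------------------------------------

def method_comparison_report(
    results,
    easy: float = 0.95,
    hard: float = 0.05,
    top_ns=DEFAULT_TOP_NS,
    out_dir=None,
) -> dict:
    """Tables comparing methods/classifiers run on a *shared* fold plan.

    Returns a dict of DataFrames: ``errors``, ``class_errors``, ``stability``,
    ``patient_matrix``, ``patients_categorized``.  If ``out_dir`` is given,
    each table is also written as CSV.
    """
    results = list(results)
    if len(results) < 1:
        raise ValueError("no CV results to report")
    plan = results[0].plan
    for res in results[1:]:
        if res.plan != plan:
            raise ValueError(
                "patient-level comparison requires all results to share one fold plan"
            )
    sample_ids = results[0].sample_ids

    err_rows, cls_rows, stab_rows, pat_rows = [], [], [], []
    acc_by_combo = {}
    for res in results:
        err_rows.append(
            {
                "method": res.method,
                "classifier": res.classifier_kind,
                "error": overall_error(res),
            }
        )
        ce = class_specific_error(res)
        cls_rows.append(
            {
                "method": res.method,
                "classifier": res.classifier_kind,
                "error_GP": ce["GP"],
                "error_PP": ce["PP"],
            }
        )
        acc = patient_accuracy(res)
        acc_by_combo[(res.method, res.classifier_kind)] = acc
        pat_rows.append(
            {
                "method": res.method,
                "classifier": res.classifier_kind,
                **{s: f for s, f in zip(sample_ids, acc.fractions())},
            }
        )

    seen_methods = set()
    for res in results:
        if res.method in seen_methods:
            continue  # selection is classifier-independent
        seen_methods.add(res.method)
        prof = stability(res.all_selected_lists(), top_ns=top_ns, method=res.method)
        row = {"method": res.method}
        for n in top_ns:
            row[f"overlap_top{n}"] = prof.overlap[n]
            row[f"fraction_top{n}"] = prof.fraction[n]
        stab_rows.append(row)

    cat_rows = []
    classifiers_seen = sorted({res.classifier_kind for res in results})
    for clf in classifiers_seen:
        accs = {m: a for (m, c), a in acc_by_combo.items() if c == clf}
        for i, s in enumerate(sample_ids):
            fracs = [a.fractions()[i] for a in accs.values()]
            if all(f >= easy for f in fracs):
                cat = "easy"
            elif all(f <= hard for f in fracs):
                cat = "hard"
            else:
                cat = "differential"
            cat_rows.append({"classifier": clf, "sample_id": s, "category": cat})

    tables = {
        "errors": pd.DataFrame(err_rows),
        "class_errors": pd.DataFrame(cls_rows),
        "stability": pd.DataFrame(stab_rows),
        "patient_matrix": pd.DataFrame(pat_rows),
        "patients_categorized": pd.DataFrame(cat_rows),
    }
    if out_dir is not None:
        import os

        os.makedirs(out_dir, exist_ok=True)
        for name, df in tables.items():
            df.to_csv(os.path.join(out_dir, f"{name}.csv"), index=False)
    return tables


def patient_matrix_heatmap(results, path):
    """Grayscale per-patient accuracy heatmap (black = correct in all rounds)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    rows = [f"{r.method}/{r.classifier_kind}" for r in results]
    mat = np.vstack([patient_accuracy(r).fractions() for r in results])
    fig, ax = plt.subplots(figsize=(max(6, mat.shape[1] * 0.2), max(2, len(rows) * 0.4)))
    ax.imshow(1.0 - mat, cmap="gray", vmin=0, vmax=1, aspect="auto")
    ax.set_yticks(range(len(rows)), rows)
    ax.set_xticks(range(mat.shape[1]), results[0].sample_ids, rotation=90, fontsize=5)
    ax.set_title("fraction of CV rounds classified correctly (black = 1)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
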