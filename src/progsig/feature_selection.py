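"""The five feature-selection methods.

All five operate on a *training* expression submatrix only and return a
:class:`RankedFeatureList`:

=============  ====================  =========================================
method         feature type          ranking statistic
=============  ====================  =========================================
``mod_t``      single genes          empirical-Bayes moderated t (p ascending)
``median_set`` gene-sets             moderated t on per-sample set medians
``netrank``    single genes          damped network propagation of the
                                     absolute expression-survival correlation
``taylor``     hub sub-networks      mean |within-class correlation difference|
                                     over hub-interactor edges
``bss_wss``    hub sub-networks      between/within sum-of-squares ratio of
                                     per-edge within-class correlations
=============  ====================  =========================================

Every method is deterministic; ties are always broken by feature id ascending.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special, stats

from .io_data import ExpressionMatrix
from .network import GeneSet, HubSubnetwork, PPINetwork

METHODS = ("mod_t", "median_set", "netrank", "taylor", "bss_wss")

_BSS_WSS_EPS = 1e-9


@dataclass
class RankedFeatureList:
    """Features ordered best-first with their ranking scores.

    ``ascending`` records whether the score is a p-value (smaller is better)
    or a plain score (larger is better).  ``extra`` carries aligned auxiliary
    per-feature arrays (e.g. moderated t statistics).
    """

    method: str
    feature_ids: tuple
    scores: tuple
    ascending: bool = False
    extra: dict = field(default_factory=dict)

    def __post_init__(self):
        self.feature_ids = tuple(self.feature_ids)
        self.scores = tuple(float(s) for s in self.scores)
        if len(self.feature_ids) != len(self.scores):
            raise ValueError("feature_ids and scores have different lengths")
        if len(set(self.feature_ids)) != len(self.feature_ids):
            raise ValueError("duplicate feature ids in ranked list")

    def __len__(self):
        return len(self.feature_ids)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "method": self.method,
                "rank": np.arange(1, len(self) + 1),
                "feature_id": list(self.feature_ids),
                "score": list(self.scores),
            }
        )
        for k, v in self.extra.items():
            df[k] = list(v)
        return df


def select_top(ranked: RankedFeatureList, n: int) -> RankedFeatureList:
    """First min(n, length) features, order preserved."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if n > len(ranked):
        warnings.warn(
            f"requested top {n} features but only {len(ranked)} available", stacklevel=2
        )
        n = len(ranked)
    return RankedFeatureList(
        method=ranked.method,
        feature_ids=ranked.feature_ids[:n],
        scores=ranked.scores[:n],
        ascending=ranked.ascending,
        extra={k: tuple(v[:n]) for k, v in ranked.extra.items()},
    )


# ---------------------------------------------------------------------------
# moderated t
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EmpiricalBayesPrior:
    """Hyperparameters of the inverse-chi-square prior on residual variances."""

    d0: float       # prior degrees of freedom; may be +inf
    s0_sq: float    # prior variance

    def __post_init__(self):
        if not (self.d0 >= 0):
            raise ValueError("d0 must be non-negative")
        if not (self.s0_sq > 0) and self.d0 > 0:
            raise ValueError("s0_sq must be positive when d0 > 0")


def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 by Newton iteration."""
    if y <= 0:
        return math.inf
    if y > 1e7:
        return 1.0 / math.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = float(special.polygamma(1, x))
        dif = tri * (1.0 - tri / y) / float(special.polygamma(2, x))
        x += dif
        if abs(dif) < 1e-10 * x:
            break
    return x


def estimate_prior(s2: np.ndarray, df: float) -> EmpiricalBayesPrior:
    """Moment-match (d0, s0^2) on log sample variances via digamma/trigamma.

    Genes with zero sample variance are excluded from the fit.  When the
    residual variances are (nearly) constant the moment equation has no
    positive solution and d0 = +inf is returned (complete shrinkage to s0^2).
    """
    s2 = np.asarray(s2, dtype=float)
    ok = s2 > 0
    if ok.sum() < 2:
        warnings.warn(
            "fewer than 2 positive sample variances; prior disabled (d0=0)", stacklevel=2
        )
        return EmpiricalBayesPrior(d0=0.0, s0_sq=float(np.max(s2, initial=1.0)) or 1.0)
    z = np.log(s2[ok])
    e = z - special.digamma(df / 2.0) + math.log(df / 2.0)
    emean = float(np.mean(e))
    n = e.size
    evar = float(np.sum((e - emean) ** 2) / (n - 1)) - float(special.polygamma(1, df / 2.0))
    if evar > 0:
        d0 = 2.0 * _trigamma_inverse(evar)
        s0_sq = math.exp(emean + float(special.digamma(d0 / 2.0)) - math.log(d0 / 2.0))
    else:
        d0 = math.inf
        s0_sq = math.exp(emean)
    return EmpiricalBayesPrior(d0=d0, s0_sq=s0_sq)


def _class_masks(labels):
    labels = np.asarray(labels, dtype=object)
    gp = labels == "GP"
    pp = labels == "PP"
    if gp.sum() + pp.sum() != labels.size:
        bad = sorted(set(labels) - {"GP", "PP"})
        raise ValueError(f"unknown class label(s): {bad}")
    return gp, pp


def moderated_t(
    expr: ExpressionMatrix,
    labels,
    prior: EmpiricalBayesPrior | None = None,
) -> RankedFeatureList:
    """Empirical-Bayes moderated two-sample t-test, ranked by p ascending.

    The per-gene pooled variance s_g^2 is shrunk towards the prior:
    ``s_tilde^2 = (d0*s0^2 + d*s_g^2) / (d0 + d)`` with d = n1+n2-2, and the
    statistic ``t = (mean_PP - mean_GP) / (s_tilde * sqrt(1/n1 + 1/n2))`` is
    referred to a t distribution on d0 + d degrees of freedom.  Pass
    ``prior=EmpiricalBayesPrior(0, ...)`` to recover the ordinary pooled t.
    """
    gp, pp = _class_masks(labels)
    n1, n2 = int(pp.sum()), int(gp.sum())
    if n1 < 2 or n2 < 2:
        raise ValueError("moderated_t requires at least 2 samples per class")
    X = expr.values
    x_pp, x_gp = X[:, pp], X[:, gp]
    diff = x_pp.mean(axis=1) - x_gp.mean(axis=1)
    d = n1 + n2 - 2
    ss = ((x_pp - x_pp.mean(axis=1, keepdims=True)) ** 2).sum(axis=1) + (
        (x_gp - x_gp.mean(axis=1, keepdims=True)) ** 2
    ).sum(axis=1)
    s2 = ss / d
    if prior is None:
        prior = estimate_prior(s2, d)
    if math.isinf(prior.d0):
        s2_post = np.full_like(s2, prior.s0_sq)
        df_total = math.inf
    else:
        s2_post = (prior.d0 * prior.s0_sq + d * s2) / (prior.d0 + d)
        df_total = prior.d0 + d
    se = np.sqrt(s2_post * (1.0 / n1 + 1.0 / n2))
    degenerate = se == 0
    if degenerate.any():
        warnings.warn(
            f"{int(degenerate.sum())} gene(s) with zero moderated variance ranked last",
            stacklevel=2,
        )
    t = np.zeros_like(diff)
    np.divide(diff, se, out=t, where=~degenerate)
    if math.isinf(df_total):
        p = 2.0 * stats.norm.sf(np.abs(t))
    else:
        p = 2.0 * stats.t.sf(np.abs(t), df_total)
    p = np.where(degenerate, 1.0, p)
    order = sorted(
        range(len(expr.gene_ids)),
        key=lambda i: (bool(degenerate[i]), p[i], expr.gene_ids[i]),
    )
    return RankedFeatureList(
        method="mod_t",
        feature_ids=tuple(expr.gene_ids[i] for i in order),
        scores=tuple(p[order]),
        ascending=True,
        extra={
            "t": tuple(t[order]),
            "d0": (float(prior.d0),) * len(order),
            "s0_sq": (float(prior.s0_sq),) * len(order),
        },
    )


# ---------------------------------------------------------------------------
# gene-set median expression
# ---------------------------------------------------------------------------

def set_median_matrix(expr: ExpressionMatrix, genesets) -> ExpressionMatrix:
    """Per-sample median over each set's measured members (sets x samples)."""
    rows, ids = [], []
    n_dropped = 0
    for gs in genesets:
        members = [m for m in gs.members if m in expr]
        if not members:
            n_dropped += 1
            continue
        rows.append(np.median(expr.rows(members), axis=0))
        ids.append(gs.set_id)
    if n_dropped:
        warnings.warn(f"dropped {n_dropped} gene-set(s) with no measured members", stacklevel=2)
    if not ids:
        raise ValueError("no gene-set has any measured member")
    return ExpressionMatrix(tuple(ids), expr.sample_ids, np.vstack(rows))


def median_set_scores(
    expr: ExpressionMatrix,
    labels,
    genesets,
    prior: EmpiricalBayesPrior | None = None,
) -> RankedFeatureList:
    """Moderated t applied to the set x sample matrix of per-sample medians."""
    med = set_median_matrix(expr, genesets)
    ranked = moderated_t(med, labels, prior=prior)
    return RankedFeatureList(
        method="median_set",
        feature_ids=ranked.feature_ids,
        scores=ranked.scores,
        ascending=True,
        extra=ranked.extra,
    )


# ---------------------------------------------------------------------------
# NetRank
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class NetRankParams:
    a: float = 0.3          # damping: weight of the network term
    tol: float = 1e-9       # L1 convergence tolerance
    max_iter: int = 1000

    def __post_init__(self):
        if not (0.0 <= self.a < 1.0):
            raise ValueError("netrank damping parameter a must be in [0, 1)")
        if not (self.tol > 0):
            raise ValueError("tol must be positive")
        if self.max_iter < 1:
            raise ValueError("max_iter must be a positive integer")


def survival_correlation(expr: ExpressionMatrix, survival) -> np.ndarray:
    """|Pearson correlation| of each gene's profile with survival time.

    Undefined correlations (zero-variance gene, or constant survival) are 0.
    """
    s = np.asarray(survival, dtype=float)
    if s.size != expr.n_samples:
        raise ValueError("survival vector length does not match sample count")
    X = expr.values
    xc = X - X.mean(axis=1, keepdims=True)
    sc = s - s.mean()
    denom = np.sqrt((xc**2).sum(axis=1)) * np.sqrt((sc**2).sum())
    c = np.zeros(X.shape[0])
    np.divide(np.abs(xc @ sc), denom, out=c, where=denom > 0)
    return c


def netrank_scores(c: np.ndarray, W, params: NetRankParams) -> tuple[np.ndarray, int]:
    """Iterate r <- (1-a) c + a M^T r with M the degree-row-normalised W.

    c is normalised to sum 1 first (if its sum is positive).  Returns the
    fixed point and the number of iterations used.  Degree-0 (dangling) rows
    of W are zero in M: such genes redistribute nothing and keep a score
    driven by their own c.
    """
    c = np.asarray(c, dtype=float)
    total = c.sum()
    if total > 0:
        c = c / total
    deg = np.asarray(W.sum(axis=1)).ravel()
    inv = np.zeros_like(deg)
    np.divide(1.0, deg, out=inv, where=deg > 0)
    # M = D^{-1} W ; we only ever need M^T r = W^T (r/deg)
    a = params.a
    r = c.copy()
    n_iter = 0
    converged = False
    for n_iter in range(1, params.max_iter + 1):
        r_new = (1.0 - a) * c + a * (W.T @ (inv * r))
        delta = float(np.abs(r_new - r).sum())
        r = r_new
        if delta < params.tol:
            converged = True
            break
    if not converged:
        warnings.warn(
            f"netrank did not converge in {params.max_iter} iterations "
            f"(returning current iterate)",
            stacklevel=2,
        )
    return r, n_iter


def netrank(
    expr: ExpressionMatrix,
    survival,
    net: PPINetwork,
    params: NetRankParams | None = None,
) -> RankedFeatureList:
    """Network-propagated expression-survival correlation ranking.

    Genes in the network are ranked by their fixed-point score descending;
    genes absent from the network are appended afterwards, ordered by their
    raw |survival correlation| descending (their ``score`` column holds that
    raw correlation and is only comparable within that tail block).
    """
    if params is None:
        params = NetRankParams()
    c_all = survival_correlation(expr, survival)
    in_net = [g for g in expr.gene_ids if g in net]
    out_net = [g for g in expr.gene_ids if g not in net]
    idx = {g: i for i, g in enumerate(expr.gene_ids)}

    ranked_ids, ranked_scores = [], []
    if in_net:
        W = net.adjacency(in_net)
        c_net = c_all[[idx[g] for g in in_net]]
        r, _ = netrank_scores(c_net, W, params)
        order = sorted(range(len(in_net)), key=lambda i: (-r[i], in_net[i]))
        ranked_ids.extend(in_net[i] for i in order)
        ranked_scores.extend(float(r[i]) for i in order)
    tail = sorted(out_net, key=lambda g: (-c_all[idx[g]], g))
    ranked_ids.extend(tail)
    ranked_scores.extend(float(c_all[idx[g]]) for g in tail)
    return RankedFeatureList(
        method="netrank",
        feature_ids=tuple(ranked_ids),
        scores=tuple(ranked_scores),
        ascending=False,
        extra={"in_network": tuple(g in net for g in ranked_ids)},
    )


# ---------------------------------------------------------------------------
# within-class edge correlations (shared by taylor and bss_wss)
# ---------------------------------------------------------------------------

def _pearson_rows(y: np.ndarray, X: np.ndarray) -> np.ndarray:
    """Pearson correlation of vector y with each row of X; undefined -> 0."""
    yc = y - y.mean()
    Xc = X - X.mean(axis=1, keepdims=True)
    denom = np.sqrt((Xc**2).sum(axis=1)) * np.sqrt((yc**2).sum())
    r = np.zeros(X.shape[0])
    np.divide(Xc @ yc, denom, out=r, where=denom > 0)
    return r


def edge_correlations(expr: ExpressionMatrix, labels, subnet: HubSubnetwork):
    """Per-edge (r_GP, r_PP): hub-interactor Pearson correlation within each class.

    Edges whose interactor is not measured are silently skipped; the returned
    list pairs each retained edge with its two correlations.  Undefined
    correlations (zero variance within a class) are set to 0 with a warning.
    """
    gp, pp = _class_masks(labels)
    if gp.sum() < 3 or pp.sum() < 3:
        raise ValueError("edge_correlations requires at least 3 samples per class")
    if subnet.hub not in expr:
        raise KeyError(f"hub {subnet.hub!r} not measured in expression matrix")
    measured = [i for i in subnet.interactors if i in expr]
    if not measured:
        return []
    hub_row = expr.row(subnet.hub)
    inter = expr.rows(measured)
    n_zero = 0
    out = []
    r_gp = _pearson_rows(hub_row[gp], inter[:, gp])
    r_pp = _pearson_rows(hub_row[pp], inter[:, pp])
    # zero-variance detection for the warning contract
    for k, g in enumerate(measured):
        if (np.ptp(inter[k, gp]) == 0 or np.ptp(hub_row[gp]) == 0) or (
            np.ptp(inter[k, pp]) == 0 or np.ptp(hub_row[pp]) == 0
        ):
            n_zero += 1
        out.append(((subnet.hub, g), float(r_gp[k]), float(r_pp[k])))
    if n_zero:
        warnings.warn(
            f"{n_zero} edge(s) with zero within-class variance; correlation set to 0",
            stacklevel=2,
        )
    return out


def taylor_score(
    expr: ExpressionMatrix,
    labels,
    subnets,
    signed: bool = False,
) -> RankedFeatureList:
    """Mean per-edge difference in within-class correlation, per hub sub-network.

    The default (``signed=False``) averages |r_GP - r_PP| so that opposite
    flips cannot cancel; the signed mean is available behind the flag.
    """
    ids, scores = [], []
    n_dropped = 0
    for sn in subnets:
        ecs = edge_correlations(expr, labels, sn)
        if not ecs:
            n_dropped += 1
            continue
        diffs = np.array([rg - rp for _, rg, rp in ecs])
        ids.append(sn.hub)
        scores.append(float(np.mean(diffs) if signed else np.mean(np.abs(diffs))))
    if n_dropped:
        warnings.warn(
            f"dropped {n_dropped} sub-network(s) with no measured interactors", stacklevel=2
        )
    order = sorted(range(len(ids)), key=lambda i: (-scores[i], ids[i]))
    return RankedFeatureList(
        method="taylor",
        feature_ids=tuple(ids[i] for i in order),
        scores=tuple(scores[i] for i in order),
        ascending=False,
    )


def bss_wss_ratio(r_gp, r_pp, eps: float = _BSS_WSS_EPS) -> tuple[float, float, float]:
    """(BSS, WSS, BSS/(WSS+eps)) treating edges as observations within class."""
    r_gp = np.asarray(r_gp, dtype=float)
    r_pp = np.asarray(r_pp, dtype=float)
    m = r_gp.size
    if m < 2 or r_pp.size != m:
        raise ValueError("need >= 2 edges with correlations in both classes")
    grand = float(np.concatenate([r_gp, r_pp]).mean())
    bss = float(sum(m * (rk.mean() - grand) ** 2 for rk in (r_gp, r_pp)))
    wss = float(sum(((rk - rk.mean()) ** 2).sum() for rk in (r_gp, r_pp)))
    return bss, wss, bss / (wss + eps)


def bss_wss_score(expr: ExpressionMatrix, labels, subnets) -> RankedFeatureList:
    """BSS/WSS ratio of per-edge within-class correlations, per hub sub-network."""
    ids, scores = [], []
    n_dropped = 0
    for sn in subnets:
        ecs = edge_correlations(expr, labels, sn)
        if len(ecs) < 2:
            n_dropped += 1
            continue
        _, _, ratio = bss_wss_ratio([rg for _, rg, _ in ecs], [rp for _, _, rp in ecs])
        ids.append(sn.hub)
        scores.append(ratio)
    if n_dropped:
        warnings.warn(
            f"dropped {n_dropped} sub-network(s) with fewer than 2 measured edges",
            stacklevel=2,
        )
    order = sorted(range(len(ids)), key=lambda i: (-scores[i], ids[i]))
    return RankedFeatureList(
        method="bss_wss",
        feature_ids=tuple(ids[i] for i in order),
        scores=tuple(scores[i] for i in order),
        ascending=False,
    )
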