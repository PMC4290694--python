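"""Independent brute-force oracles, coded separately from the package internals.

These deliberately use plain per-gene loops and different numerical solvers
(brentq root finding instead of Newton iteration, dense linear solves instead
of power iteration) so that agreement with the pipeline is informative.
"""

import math

import numpy as np
from scipy import optimize, special, stats


def oracle_prior(s2, d):
    """Moment-match (d0, s0_sq) using a bracketing root finder on trigamma."""
    s2 = [v for v in s2 if v > 0]
    e = [math.log(v) - float(special.digamma(d / 2)) + math.log(d / 2) for v in s2]
    n = len(e)
    ebar = sum(e) / n
    evar = sum((x - ebar) ** 2 for x in e) / (n - 1) - float(special.polygamma(1, d / 2))
    if evar <= 0:
        return math.inf, math.exp(ebar)
    f = lambda x: float(special.polygamma(1, x)) - evar
    # trigamma is strictly decreasing on (0, inf)
    lo, hi = 1e-8, 1e8
    x = optimize.brentq(f, lo, hi, xtol=1e-14, rtol=8.9e-16, maxiter=200)
    d0 = 2.0 * x
    s0_sq = math.exp(ebar + float(special.digamma(d0 / 2)) - math.log(d0 / 2))
    return d0, s0_sq


def oracle_moderated_t(values, labels, d0=None, s0_sq=None):
    """Per-gene loop implementation; returns (t, p, d0, s0_sq) arrays/values."""
    labels = list(labels)
    pp = [i for i, l in enumerate(labels) if l == "PP"]
    gp = [i for i, l in enumerate(labels) if l == "GP"]
    n1, n2 = len(pp), len(gp)
    d = n1 + n2 - 2
    s2 = []
    diffs = []
    for row in values:
        x1 = [row[i] for i in pp]
        x2 = [row[i] for i in gp]
        m1 = sum(x1) / n1
        m2 = sum(x2) / n2
        ss = sum((v - m1) ** 2 for v in x1) + sum((v - m2) ** 2 for v in x2)
        s2.append(ss / d)
        diffs.append(m1 - m2)
    if d0 is None:
        d0, s0_sq = oracle_prior(s2, d)
    ts, ps = [], []
    for sg2, diff in zip(s2, diffs):
        if math.isinf(d0):
            post = s0_sq
            df = math.inf
        else:
            post = (d0 * s0_sq + d * sg2) / (d0 + d)
            df = d0 + d
        se = math.sqrt(post * (1 / n1 + 1 / n2))
        if se == 0:
            ts.append(0.0)
            ps.append(1.0)
            continue
        t = diff / se
        if math.isinf(df):
            pv = 2 * stats.norm.sf(abs(t))
        else:
            pv = 2 * stats.t.sf(abs(t), df)
        ts.append(t)
        ps.append(pv)
    return np.array(ts), np.array(ps), d0, s0_sq


def oracle_netrank(c, W_dense, a):
    """Direct dense solve of (I - a M^T) r = (1 - a) c_norm."""
    c = np.asarray(c, dtype=float)
    if c.sum() > 0:
        c = c / c.sum()
    W = np.asarray(W_dense, dtype=float)
    deg = W.sum(axis=1)
    M = np.zeros_like(W)
    for i in range(W.shape[0]):
        if deg[i] > 0:
            M[i] = W[i] / deg[i]
    n = W.shape[0]
    return np.linalg.solve(np.eye(n) - a * M.T, (1 - a) * c)


def oracle_pairwise_overlap(lists, n):
    """Mean |top-n intersection| over all unordered pairs, by enumeration."""
    tops = [set(l[:n]) for l in lists]
    total, pairs = 0, 0
    for i in range(len(tops)):
        for j in range(i + 1, len(tops)):
            total += len(tops[i] & tops[j])
            pairs += 1
    return total / pairs


def oracle_dlda_predict(train_values, train_labels, test_values):
    """Exhaustive two-class diagonal discriminant scoring with loops."""
    classes = ["GP", "PP"]
    train_labels = list(train_labels)
    n_feat = len(train_values)
    means = {}
    for k in classes:
        cols = [i for i, l in enumerate(train_labels) if l == k]
        means[k] = [sum(train_values[g][i] for i in cols) / len(cols) for g in range(n_feat)]
    n = len(train_labels)
    var = []
    for g in range(n_feat):
        ss = 0.0
        for k in classes:
            cols = [i for i, l in enumerate(train_labels) if l == k]
            for i in cols:
                ss += (train_values[g][i] - means[k][g]) ** 2
        var.append(ss / (n - 2))
    preds = []
    for j in range(len(test_values[0])):
        scores = {}
        for k in classes:
            scores[k] = sum(
                (test_values[g][j] - means[k][g]) ** 2 / var[g] for g in range(n_feat)
            )
        preds.append("GP" if scores["GP"] <= scores["PP"] else "PP")
    return preds
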