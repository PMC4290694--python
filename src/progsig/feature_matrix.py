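"""Turn selected features into per-sample numeric classification features.

Every builder here is per-sample independent: a sample's feature column
depends only on that sample's expression values and the (frozen) feature
definitions, never on other samples.  This is what makes it legal to freeze
feature definitions on a training fold and apply them to test samples.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_data import ExpressionMatrix


@dataclass
class FeatureValueMatrix:
    """Features x samples numeric matrix consumed by the classifiers."""

    feature_ids: tuple
    sample_ids: tuple
    values: np.ndarray

    def __post_init__(self):
        self.feature_ids = tuple(str(f) for f in self.feature_ids)
        self.sample_ids = tuple(str(s) for s in self.sample_ids)
        self.values = np.asarray(self.values, dtype=float)
        if len(set(self.feature_ids)) != len(self.feature_ids):
            raise ValueError("duplicate feature ids")
        if self.values.shape != (len(self.feature_ids), len(self.sample_ids)):
            raise ValueError("value matrix shape does not match feature/sample ids")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("feature values must be finite")

    @property
    def shape(self):
        return self.values.shape

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=list(self.feature_ids), columns=list(self.sample_ids)
        )

    def write_tsv(self, path):
        df = self.to_frame()
        df.index.name = "feature_id"
        df.to_csv(path, sep="\t")


def gene_features(expr: ExpressionMatrix, genes) -> FeatureValueMatrix:
    """Rows are the selected genes' expression rows, in selection order."""
    genes = list(genes)
    if not genes:
        raise ValueError("at least one gene is required")
    return FeatureValueMatrix(tuple(genes), expr.sample_ids, expr.rows(genes))


def set_median_features(expr: ExpressionMatrix, sets) -> FeatureValueMatrix:
    """One row per gene-set: the per-sample median over measured members."""
    sets = list(sets)
    if not sets:
        raise ValueError("at least one gene-set is required")
    rows, ids = [], []
    for gs in sets:
        members = [m for m in gs.members if m in expr]
        if not members:
            raise ValueError(f"gene-set {gs.set_id!r} has no measured members")
        rows.append(np.median(expr.rows(members), axis=0))
        ids.append(gs.set_id)
    return FeatureValueMatrix(tuple(ids), expr.sample_ids, np.vstack(rows))


def edge_difference_features(expr: ExpressionMatrix, subnets) -> FeatureValueMatrix:
    """One row per hub-interactor edge: expr(hub) - expr(interactor).

    Row ids are ``hub|interactor``.  Edges with unmeasured genes are dropped;
    identical edges appearing in several selected sub-networks are kept once.
    """
    rows, ids, seen = [], [], set()
    for sn in subnets:
        if sn.hub not in expr:
            continue
        hub_row = expr.row(sn.hub)
        for interactor in sn.interactors:
            if interactor not in expr:
                continue
            key = f"{sn.hub}|{interactor}"
            if key in seen:
                continue
            seen.add(key)
            ids.append(key)
            rows.append(hub_row - expr.row(interactor))
    if not ids:
        raise ValueError("no measurable hub-interactor edges in the selected sub-networks")
    return FeatureValueMatrix(tuple(ids), expr.sample_ids, np.vstack(rows))


def hub_gene_features(expr: ExpressionMatrix, subnets) -> FeatureValueMatrix:
    """Rows are the selected sub-networks' hub expression rows (deduplicated)."""
    hubs = []
    for sn in subnets:
        if sn.hub not in hubs:
            hubs.append(sn.hub)
    if not hubs:
        raise ValueError("at least one hub sub-network is required")
    missing = [h for h in hubs if h not in expr]
    if missing:
        raise KeyError(f"hub gene(s) not measured: {missing}")
    return gene_features(expr, hubs)
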