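"""Input/output and alignment of expression matrices, phenotype tables and networks.

File formats
------------
Expression: TSV, header ``gene_id<TAB>S1<TAB>S2...``, one row per gene, numeric body.
Phenotype:  TSV with header ``sample_id<TAB>class<TAB>survival_time``; class is
``GP``/``PP`` (case-insensitive), survival_time a non-negative number of years.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import AlignmentError, FormatError
from .network import PPINetwork

logger = logging.getLogger(__name__)

CLASS_LABELS = ("GP", "PP")


@dataclass
class ExpressionMatrix:
    """Log-scale expression values, genes in rows, samples in columns."""

    gene_ids: tuple
    sample_ids: tuple
    values: np.ndarray

    def __post_init__(self):
        self.gene_ids = tuple(str(g) for g in self.gene_ids)
        self.sample_ids = tuple(str(s) for s in self.sample_ids)
        self.values = np.asarray(self.values, dtype=float)
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise FormatError("duplicate gene identifiers")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise FormatError("duplicate sample identifiers")
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise FormatError(
                f"value matrix shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        if not np.all(np.isfinite(self.values)):
            i, j = np.argwhere(~np.isfinite(self.values))[0]
            raise FormatError(
                f"missing or non-finite value at gene {self.gene_ids[i]!r}, "
                f"sample {self.sample_ids[j]!r}"
            )
        self._gene_index = {g: i for i, g in enumerate(self.gene_ids)}

    @property
    def shape(self):
        return self.values.shape

    @property
    def n_samples(self):
        return len(self.sample_ids)

    def __contains__(self, gene):
        return gene in self._gene_index

    def gene_index(self, gene):
        try:
            return self._gene_index[gene]
        except KeyError:
            raise KeyError(f"unknown gene {gene!r}") from None

    def row(self, gene):
        return self.values[self.gene_index(gene)]

    def rows(self, genes):
        return self.values[[self.gene_index(g) for g in genes]]

    def subset_samples(self, sample_ids):
        idx = [self.sample_ids.index(s) for s in sample_ids]
        return ExpressionMatrix(self.gene_ids, sample_ids, self.values[:, idx])

    def subset_samples_by_index(self, idx):
        idx = np.asarray(idx)
        return ExpressionMatrix(
            self.gene_ids, tuple(self.sample_ids[i] for i in idx), self.values[:, idx]
        )

    def to_frame(self):
        return pd.DataFrame(self.values, index=list(self.gene_ids), columns=list(self.sample_ids))

    def __eq__(self, other):
        if not isinstance(other, ExpressionMatrix):
            return NotImplemented
        return (
            self.gene_ids == other.gene_ids
            and self.sample_ids == other.sample_ids
            and np.array_equal(self.values, other.values)
        )


@dataclass
class PhenotypeTable:
    """Per-sample prognosis class (GP/PP) and survival time in years."""

    sample_ids: tuple
    classes: np.ndarray
    survival: np.ndarray

    def __post_init__(self):
        self.sample_ids = tuple(str(s) for s in self.sample_ids)
        self.classes = np.asarray(self.classes, dtype=object)
        self.survival = np.asarray(self.survival, dtype=float)
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise FormatError("duplicate sample identifiers in phenotype table")
        if not (len(self.sample_ids) == len(self.classes) == len(self.survival)):
            raise FormatError("phenotype columns have unequal lengths")
        bad = sorted(set(self.classes) - set(CLASS_LABELS))
        if bad:
            raise FormatError(
                f"unknown class token(s) {bad}; allowed tokens are {list(CLASS_LABELS)}"
            )
        if len(set(self.classes)) < 2:
            raise FormatError("both classes (GP and PP) must be present")
        if not np.all(np.isfinite(self.survival)):
            raise FormatError("survival_time must be finite for every sample")
        if np.any(self.survival < 0):
            raise FormatError("survival_time must be non-negative")

    def __len__(self):
        return len(self.sample_ids)

    def subset(self, sample_ids):
        pos = {s: i for i, s in enumerate(self.sample_ids)}
        idx = [pos[s] for s in sample_ids]
        return PhenotypeTable(sample_ids, self.classes[idx], self.survival[idx])

    def class_counts(self):
        return {k: int(np.sum(self.classes == k)) for k in CLASS_LABELS}

    def __eq__(self, other):
        if not isinstance(other, PhenotypeTable):
            return NotImplemented
        return (
            self.sample_ids == other.sample_ids
            and np.array_equal(self.classes, other.classes)
            and np.array_equal(self.survival, other.survival)
        )


@dataclass
class AlignedDataset:
    """Expression, phenotype and network restricted to a shared gene/sample universe."""

    expression: ExpressionMatrix
    phenotype: PhenotypeTable
    network: PPINetwork = field(default_factory=lambda: PPINetwork([]))

    def __post_init__(self):
        if self.expression.sample_ids != self.phenotype.sample_ids:
            raise AlignmentError("expression and phenotype sample orders differ; call align()")
        missing = [n for n in self.network.nodes if n not in self.expression]
        if missing:
            raise AlignmentError(
                f"{len(missing)} network node(s) absent from expression (e.g. {missing[0]!r})"
            )

    @property
    def labels(self):
        return self.phenotype.classes

    @property
    def survival(self):
        return self.phenotype.survival


def read_expression(path) -> ExpressionMatrix:
    """Read a genes x samples TSV; duplicate gene rows keep the highest-variance row."""
    try:
        df = pd.read_csv(path, sep="\t", index_col=0, dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError:
        raise FormatError(f"{path}: empty expression file") from None
    if df.shape[1] == 0:
        raise FormatError(f"{path}: expression file has no sample columns")
    genes = [str(g) for g in df.index]
    samples = [str(s) for s in df.columns]
    raw = df.to_numpy(dtype=object)
    try:
        # numpy's parser round-trips float64 exactly (pandas' fast path does not)
        values = raw.astype(float)
    except ValueError:
        for i in range(raw.shape[0]):
            for j in range(raw.shape[1]):
                try:
                    float(raw[i, j])
                except (TypeError, ValueError):
                    raise FormatError(
                        f"{path}: non-numeric or missing value at gene {genes[i]!r}, "
                        f"sample {samples[j]!r}"
                    ) from None
        raise
    if np.isnan(values).any():
        i, j = np.argwhere(np.isnan(values))[0]
        raise FormatError(
            f"{path}: non-numeric or missing value at gene {genes[i]!r}, sample {samples[j]!r}"
        )

    if len(set(genes)) != len(genes):
        order = pd.Index(genes)
        keep = np.ones(len(genes), dtype=bool)
        variances = values.var(axis=1)
        dupes = sorted(set(g for g in genes if order.get_indexer_for([g]).size > 1))
        for g in dupes:
            rows = np.flatnonzero(np.asarray(genes) == g)
            best = rows[np.argmax(variances[rows])]
            for r in rows:
                if r != best:
                    keep[r] = False
        warnings.warn(
            f"{len(genes) - int(keep.sum())} duplicate gene row(s) dropped "
            f"(kept highest-variance row) for: {', '.join(dupes[:10])}",
            stacklevel=2,
        )
        logger.info("dropped %d duplicate gene rows", len(genes) - int(keep.sum()))
        genes = [g for g, k in zip(genes, keep) if k]
        values = values[keep]
    return ExpressionMatrix(tuple(genes), tuple(samples), values)


def write_expression(expr: ExpressionMatrix, path):
    # repr() round-trips float64 exactly; pandas' to_csv may not
    with open(path, "w") as fh:
        fh.write("gene_id\t" + "\t".join(expr.sample_ids) + "\n")
        for g, row in zip(expr.gene_ids, expr.values):
            fh.write(g + "\t" + "\t".join(repr(float(v)) for v in row) + "\n")


def read_phenotype(path) -> PhenotypeTable:
    """Read a sample_id / class / survival_time TSV (class case-insensitive)."""
    try:
        df = pd.read_csv(path, sep="\t", dtype=str)
    except pd.errors.EmptyDataError:
        raise FormatError(f"{path}: empty phenotype file") from None
    required = ["sample_id", "class", "survival_time"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: phenotype file missing column(s) {missing}")
    samples = [str(s) for s in df["sample_id"]]
    classes = []
    for s, tok in zip(samples, df["class"]):
        tok_up = str(tok).strip().upper()
        if tok_up not in CLASS_LABELS:
            raise FormatError(
                f"{path}: unknown class token {tok!r} for sample {s!r}; "
                f"allowed tokens are {list(CLASS_LABELS)}"
            )
        classes.append(tok_up)
    surv = []
    for s, v in zip(samples, df["survival_time"]):
        try:
            t = float(v)
        except (TypeError, ValueError):
            t = float("nan")
        if not np.isfinite(t):
            raise FormatError(
                f"{path}: missing or non-numeric survival_time for sample {s!r}"
            )
        surv.append(t)
    return PhenotypeTable(tuple(samples), np.array(classes, dtype=object), np.array(surv))


def write_phenotype(pheno: PhenotypeTable, path):
    with open(path, "w") as fh:
        fh.write("sample_id\tclass\tsurvival_time\n")
        for s, k, t in zip(pheno.sample_ids, pheno.classes, pheno.survival):
            fh.write(f"{s}\t{k}\t{repr(float(t))}\n")


def align(expr: ExpressionMatrix, pheno: PhenotypeTable, net: PPINetwork | None = None) -> AlignedDataset:
    """Restrict the three inputs to shared samples/genes.

    Sample order follows the expression column order (canonical); the phenotype
    table is reordered to match.  Network nodes absent from the expression
    matrix are dropped together with their edges.
    """
    if net is None:
        net = PPINetwork([])
    shared = [s for s in expr.sample_ids if s in set(pheno.sample_ids)]
    if not shared:
        raise AlignmentError("expression and phenotype share no samples")
    dropped_expr = len(expr.sample_ids) - len(shared)
    dropped_pheno = len(pheno.sample_ids) - len(shared)
    if dropped_expr or dropped_pheno:
        logger.info(
            "align: dropped %d expression-only and %d phenotype-only sample(s)",
            dropped_expr,
            dropped_pheno,
        )
    shared_set = set(shared)
    counts = {
        k: sum(
            1 for s, c in zip(pheno.sample_ids, pheno.classes) if c == k and s in shared_set
        )
        for k in CLASS_LABELS
    }
    for k, c in counts.items():
        if c == 0:
            raise AlignmentError(f"class {k} has no samples after alignment")
        if c < 2:
            raise AlignmentError(f"class {k} has fewer than 2 samples after alignment")
    expr2 = expr.subset_samples(tuple(shared)) if dropped_expr else expr
    pheno2 = pheno.subset(tuple(shared))

    keep_nodes = [n for n in net.nodes if n in expr2]
    n_drop_nodes = net.n_nodes - len(keep_nodes)
    net2 = net.subgraph(keep_nodes) if n_drop_nodes else net
    if n_drop_nodes:
        logger.info(
            "align: dropped %d network node(s) and %d edge(s) absent from expression",
            n_drop_nodes,
            net.n_edges - net2.n_edges,
        )
    return AlignedDataset(expr2, pheno2, net2)
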