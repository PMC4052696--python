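"""Differential-expression scores and co-expression statistics.

The node cost used by the path optimiser is the DES (differential
expression score): a gene's two-sided equal-variance Student's t-test
P-value between case and control samples, averaged over every dataset in
which the gene is measured.  Genes never measured get DES = 1.0 (maximal
cost), so paths prefer proteins backed by expression evidence.  Pearson
correlation (pooled over samples) supports orphan-gene attachment, and
log2 fold change supports paired designs too small for correlation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

from .graph_io import ExpressionDataset

__all__ = [
    "students_t_p",
    "DESTable",
    "build_des_table",
    "CorrelationRecord",
    "pearson_r",
    "dataset_correlation",
    "fold_change",
]

#: DES assigned to genes absent from every dataset
UNMEASURED_DES = 1.0


def students_t_p(case_values, control_values) -> float:
    """Two-sided equal-variance two-sample t-test P-value.

    Degenerate zero-pooled-variance inputs resolve to p = 1 when the group
    means agree and p = 0 when they differ (an infinite t statistic).
    """
    x = np.asarray(case_values, dtype=float)
    y = np.asarray(control_values, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each group needs at least 2 values")
    vx = np.var(x, ddof=1)
    vy = np.var(y, ddof=1)
    if vx == 0 and vy == 0:
        return 1.0 if np.mean(x) == np.mean(y) else 0.0
    return float(sps.ttest_ind(x, y, equal_var=True).pvalue)


@dataclass
class DESTable:
    """Per-gene DES with the per-dataset P-values behind it."""

    p_values: dict[str, list[float]] = field(default_factory=dict)

    def des(self, gene: str) -> float:
        ps = self.p_values.get(gene)
        if not ps:
            return UNMEASURED_DES
        return float(np.mean(ps))

    def n_datasets_observed(self, gene: str) -> int:
        return len(self.p_values.get(gene, ()))

    def __getitem__(self, gene: str) -> float:
        return self.des(gene)

    def genes(self) -> list[str]:
        return sorted(self.p_values)

    def to_rows(self) -> list[dict]:
        return [
            {"gene": g, "des": self.des(g),
             "n_datasets_observed": self.n_datasets_observed(g)}
            for g in self.genes()
        ]


def build_des_table(datasets: list[ExpressionDataset],
                    genes=None) -> DESTable:
    """Average each gene's t-test P-value over the datasets measuring it.

    ``genes`` restricts and seeds the table (unmeasured entries fall back
    to DES = 1.0); by default every gene in any dataset is scored.
    """
    if not datasets:
        raise ValueError("at least one expression dataset is required")
    if genes is None:
        genes = sorted({g for ds in datasets for g in ds.genes})
    table = DESTable()
    for gene in genes:
        ps = []
        for ds in datasets:
            if gene in ds:
                case, control = ds.case_control(gene)
                ps.append(students_t_p(case, control))
        if ps:
            table.p_values[gene] = ps
    return table


@dataclass(frozen=True)
class CorrelationRecord:
    gene_a: str
    gene_b: str
    r: float
    sign: str  # "positive" | "negative"


def pearson_r(x_values, y_values, gene_a: str = "x",
              gene_b: str = "y") -> CorrelationRecord:
    """Pearson correlation between two expression vectors (n >= 3)."""
    x = np.asarray(x_values, dtype=float)
    y = np.asarray(y_values, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("vectors must have equal length >= 3")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("correlation is undefined for a constant vector")
    r = float(sps.pearsonr(x, y).statistic)
    return CorrelationRecord(gene_a=gene_a, gene_b=gene_b, r=r,
                             sign="positive" if r >= 0 else "negative")


def dataset_correlation(datasets: list[ExpressionDataset], gene_a: str,
                        gene_b: str) -> CorrelationRecord | None:
    """Mean Pearson r over datasets measuring both genes (None if none do,
    or if either gene is constant wherever both appear)."""
    rs = []
    for ds in datasets:
        if gene_a in ds and gene_b in ds:
            try:
                rs.append(pearson_r(ds.expression(gene_a),
                                    ds.expression(gene_b)).r)
            except ValueError:
                continue
    if not rs:
        return None
    r = float(np.mean(rs))
    return CorrelationRecord(gene_a=gene_a, gene_b=gene_b, r=r,
                             sign="positive" if r >= 0 else "negative")


def fold_change(case_value: float, control_value: float) -> float:
    """log2(case / control); both values must be positive."""
    if case_value <= 0 or control_value <= 0:
        raise ValueError("fold change requires positive expression values")
    return float(np.log2(case_value / control_value))
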