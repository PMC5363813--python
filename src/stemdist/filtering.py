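"""IQR-based gene filtering.

A gene g_i is retained when

    max(g_i) >= log2(100)                 (expression floor)
    and IQR(g_i) >= c * median(IQR(g))    (variability cutoff)

with the interquartile range taken across samples under the linear-
interpolation quantile convention, and the median taken over *all* genes
(including floor-failing ones). ``c`` is a unitless tuning parameter: c = 0
keeps every floor-passing gene; on matrices with distinct IQRs all above the
floor, c = 1 keeps exactly the more variable half.

The retained-fraction form retains the top ``ceil(fraction * n_genes)`` genes
by IQR among floor-passing genes, which is how the tuning grid (top 5%, 10%,
..., 95%) is expressed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from math import ceil

import numpy as np

from .io_core import ExpressionMatrix

__all__ = [
    "EXPRESSION_FLOOR",
    "FilterMask",
    "gene_iqr",
    "apply_gene_filter",
    "filter_by_retained_fraction",
    "default_fraction_grid",
    "write_filter_mask",
    "read_filter_mask",
]

#: Expression floor in log2 units: genes never reaching log2(100) are treated
#: as consistently low-expressed background and removed before the IQR cutoff.
EXPRESSION_FLOOR: float = float(np.log2(100.0))


@dataclass
class FilterMask:
    """Result of a gene filter: the retained genes plus the parameters used."""

    gene_ids: list[str]
    c: float
    retained_fraction: float
    floor: float = EXPRESSION_FLOOR

    def __post_init__(self) -> None:
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("filter mask contains duplicate gene ids")
        if not (0.0 < self.retained_fraction <= 1.0) and self.gene_ids:
            raise ValueError("retained_fraction must be in (0, 1] for a non-empty mask")

    def __len__(self) -> int:
        return len(self.gene_ids)


def gene_iqr(expr: ExpressionMatrix) -> np.ndarray:
    """Per-gene interquartile range across samples (75th - 25th percentile)."""
    if expr.n_samples < 2:
        raise ValueError("IQR requires at least 2 samples")
    q75, q25 = np.percentile(expr.values, [75, 25], axis=1)
    return q75 - q25


def _floor_pass(expr: ExpressionMatrix) -> np.ndarray:
    return expr.values.max(axis=1) >= EXPRESSION_FLOOR


def apply_gene_filter(expr: ExpressionMatrix, c: float) -> FilterMask:
    """Apply the filter in its c-parameterized form.

    Retains genes with max expression >= log2(100) and IQR >= c * median(IQR),
    the median taken over all genes of the matrix.
    """
    if not np.isfinite(c) or c < 0:
        raise ValueError(f"tuning parameter c must be finite and >= 0, got {c!r}")
    iqr = gene_iqr(expr)
    med = float(np.median(iqr))
    keep = _floor_pass(expr) & (iqr >= c * med)
    gene_ids = [g for g, k in zip(expr.gene_ids, keep) if k]
    frac = len(gene_ids) / expr.n_genes if expr.n_genes else 0.0
    return FilterMask(gene_ids, c=float(c), retained_fraction=frac)


def filter_by_retained_fraction(expr: ExpressionMatrix, fraction: float) -> FilterMask:
    """Apply the filter in its retained-fraction form.

    The expression floor is applied first; then the ``ceil(fraction * n_genes)``
    genes with highest IQR among floor-passing genes are retained (all of them
    if fewer remain). IQR ties break by gene-id lexicographic order. The
    reported ``c`` is the equivalent cutoff, smallest retained IQR divided by
    the median IQR over all genes.
    """
    if not (0.0 < fraction <= 1.0):
        raise ValueError(f"fraction must be in (0, 1], got {fraction!r}")
    iqr = gene_iqr(expr)
    med = float(np.median(iqr))
    passing = np.flatnonzero(_floor_pass(expr))
    if passing.size == 0:
        return FilterMask([], c=float("inf"), retained_fraction=0.0)
    k = min(ceil(fraction * expr.n_genes), passing.size)
    order = sorted(passing, key=lambda i: (-iqr[i], expr.gene_ids[i]))
    chosen = order[:k]
    min_iqr = min(iqr[i] for i in chosen)
    c_equiv = min_iqr / med if med > 0 else 0.0
    keep_set = set(chosen)
    gene_ids = [expr.gene_ids[i] for i in sorted(keep_set)]  # original gene order
    return FilterMask(gene_ids, c=float(c_equiv), retained_fraction=k / expr.n_genes)


def default_fraction_grid() -> list[float]:
    """The tuning grid of retained fractions: 0.05, 0.10, ..., 0.95 (19 levels)."""
    return [round(0.05 * i, 2) for i in range(1, 20)]


def write_filter_mask(mask: FilterMask, gene_path, meta_path) -> None:
    """Write the retained gene ids as one-column TSV plus a JSON parameter sidecar."""
    with open(gene_path, "w") as fh:
        fh.write("gene\n")
        for g in mask.gene_ids:
            fh.write(f"{g}\n")
    with open(meta_path, "w") as fh:
        json.dump(
            {"c": mask.c, "retained_fraction": mask.retained_fraction, "floor": mask.floor},
            fh,
            indent=2,
        )


def read_filter_mask(gene_path, meta_path) -> FilterMask:
    with open(gene_path) as fh:
        lines = [ln.strip() for ln in fh if ln.strip()]
    if not lines or lines[0] != "gene":
        raise ValueError(f"{gene_path} is not a filter-mask gene list (missing 'gene' header)")
    with open(meta_path) as fh:
        meta = json.load(fh)
    return FilterMask(lines[1:], c=meta["c"], retained_fraction=meta["retained_fraction"], floor=meta["floor"])
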