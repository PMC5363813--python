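"""Stem-cell reference centroids and per-sample expression distances.

A reference profile is the per-gene mean of a small set of stem-cell samples
(e.g. hESC, hMSC or CD34+ replicates). Each tumor sample's distance from that
centroid — Pearson correlation distance (1 - r, in [0, 2]) or Euclidean
distance in log2 units — is computed over an IQR-filtered gene set. Smaller
distance means the sample looks more stem-like, which is the high-risk
orientation for survival.

The filter mask is expected to come from the patient cohort's own IQRs; the
reference samples never enter the IQR pool. Genes in the mask that the
reference does not carry are dropped with a warning (intersection semantics).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .filtering import FilterMask
from .io_core import ExpressionMatrix

logger = logging.getLogger("stemdist")

__all__ = [
    "ReferenceProfile",
    "DistanceVector",
    "reference_centroid",
    "profile_distance",
    "stem_cell_distances",
]

METRICS = ("pearson", "euclidean")


@dataclass
class ReferenceProfile:
    """Per-gene centroid of a stem-cell reference (label e.g. hESC/hMSC/CD34+)."""

    label: str
    gene_ids: list[str]
    centroid: np.ndarray
    n_samples: int

    def __post_init__(self) -> None:
        self.centroid = np.asarray(self.centroid, dtype=float)
        if self.centroid.shape != (len(self.gene_ids),):
            raise ValueError("centroid length does not match gene count")
        if not np.all(np.isfinite(self.centroid)):
            raise ValueError("non-finite centroid value")
        if self.n_samples < 1:
            raise ValueError("reference must average at least one sample")

    def subset_genes(self, gene_ids) -> "ReferenceProfile":
        index = {g: i for i, g in enumerate(self.gene_ids)}
        rows = [index[g] for g in gene_ids]
        return ReferenceProfile(self.label, list(gene_ids), self.centroid[rows], self.n_samples)


@dataclass
class DistanceVector:
    """Per-sample distances to one reference centroid."""

    sample_ids: list[str]
    distances: np.ndarray
    metric: str
    reference_label: str
    n_genes_used: int

    def __post_init__(self) -> None:
        self.distances = np.asarray(self.distances, dtype=float)
        if self.distances.shape != (len(self.sample_ids),):
            raise ValueError("distance length does not match sample count")
        if not np.all(np.isfinite(self.distances)):
            raise ValueError("non-finite distance")
        if self.metric == "pearson" and (
            np.any(self.distances < -1e-12) or np.any(self.distances > 2 + 1e-12)
        ):
            raise ValueError("pearson distances must lie in [0, 2]")
        if self.metric == "euclidean" and np.any(self.distances < 0):
            raise ValueError("euclidean distances must be non-negative")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sample": self.sample_ids,
                "distance": self.distances,
                "metric": self.metric,
                "reference": self.reference_label,
                "n_genes": self.n_genes_used,
            }
        )

    def write(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, float_format="%.17g")


def reference_centroid(ref_expr: ExpressionMatrix, label: str) -> ReferenceProfile:
    """Average replicate stem-cell samples into a per-gene centroid."""
    if ref_expr.n_samples < 1 or ref_expr.n_genes < 1:
        raise ValueError("reference expression matrix is empty")
    return ReferenceProfile(
        label=label,
        gene_ids=list(ref_expr.gene_ids),
        centroid=ref_expr.values.mean(axis=1),
        n_samples=ref_expr.n_samples,
    )


def profile_distance(x, y, metric: str) -> float:
    """Distance between two expression profiles.

    pearson -> 1 - Pearson correlation coefficient (in [0, 2]);
    euclidean -> sqrt(sum((x - y)^2)).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("profiles must be 1-D vectors of equal length")
    if x.size < 3:
        raise ValueError("profile distance requires at least 3 genes")
    if metric == "euclidean":
        return float(np.sqrt(np.sum((x - y) ** 2)))
    if metric == "pearson":
        xc = x - x.mean()
        yc = y - y.mean()
        nx = np.sqrt(np.sum(xc**2))
        ny = np.sqrt(np.sum(yc**2))
        if nx == 0 or ny == 0:
            raise ValueError("Pearson correlation undefined for a constant profile")
        r = float(np.dot(xc, yc) / (nx * ny))
        return float(np.clip(1.0 - r, 0.0, 2.0))
    raise ValueError(f"unknown metric {metric!r}; expected one of {METRICS}")


def stem_cell_distances(
    expr: ExpressionMatrix,
    ref: ReferenceProfile,
    mask: FilterMask,
    metric: str,
) -> DistanceVector:
    """Distance of every sample from the reference centroid over the masked genes.

    Mask genes missing from ``expr`` are an error; mask genes missing from the
    reference are dropped with a warning (intersection semantics). At least 3
    genes must survive.
    """
    if metric not in METRICS:
        raise ValueError(f"unknown metric {metric!r}; expected one of {METRICS}")
    expr_genes = set(expr.gene_ids)
    missing_expr = [g for g in mask.gene_ids if g not in expr_genes]
    if missing_expr:
        raise ValueError(f"mask gene(s) absent from expression matrix: {missing_expr[:10]}")
    ref_genes = set(ref.gene_ids)
    genes = [g for g in mask.gene_ids if g in ref_genes]
    dropped = len(mask.gene_ids) - len(genes)
    if dropped:
        warnings.warn(
            f"{dropped} masked gene(s) absent from reference {ref.label!r} were dropped",
            stacklevel=2,
        )
    if len(genes) < 3:
        raise ValueError(
            f"only {len(genes)} gene(s) shared between mask and reference "
            f"{ref.label!r}; need >= 3"
        )
    sub = expr.subset_genes(genes)
    cen = ref.subset_genes(genes).centroid
    X = sub.values  # genes x samples
    if metric == "euclidean":
        d = np.sqrt(np.sum((X - cen[:, None]) ** 2, axis=0))
    else:
        Xc = X - X.mean(axis=0, keepdims=True)
        cc = cen - cen.mean()
        nx = np.sqrt(np.sum(Xc**2, axis=0))
        nc = np.sqrt(np.sum(cc**2))
        if nc == 0:
            raise ValueError("Pearson correlation undefined: constant reference centroid")
        const = np.flatnonzero(nx == 0)
        if const.size:
            raise ValueError(
                "Pearson correlation undefined for constant sample profile(s): "
                f"{[sub.sample_ids[i] for i in const[:10]]}"
            )
        r = (Xc.T @ cc) / (nx * nc)
        d = np.clip(1.0 - r, 0.0, 2.0)
    return DistanceVector(
        sample_ids=list(expr.sample_ids),
        distances=d,
        metric=metric,
        reference_label=ref.label,
        n_genes_used=len(genes),
    )
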