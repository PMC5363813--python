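"""Gene signatures derived from stem-cell distances.

Within each cohort, every gene's (zero-variance genes excluded) expression is
standardized to mean 0, SD 1, and the stem-cell distance is regressed on it by
ordinary least squares, giving a slope beta (distance units per expression SD)
and a residual-based standard error with n - 2 degrees of freedom.
Standardizing inside each cohort makes the slopes comparable across cohorts
and platforms, so they can be pooled by an inverse-variance fixed-effects
meta-analysis:

    w_k = 1 / se_k^2,   pooled_beta = sum(w_k beta_k) / sum(w_k),
    pooled_se = 1 / sqrt(sum(w_k)),   z = pooled_beta / pooled_se.

Genes are ranked by |z| (meta-analytic significance; |beta| ranking available
as an option) and the top k form the signature: 500 genes for enrichment-scale
use, the top 200 for survival scoring. A sample's risk score is the weighted
sum of its standardized expression over the signature genes, positive weights
adding and negative weights subtracting. The score tracks the *distance*, so
high score = far from stem cells = low risk; flip the sign (or the reported
hazard ratio's direction) when presenting it as a risk of death.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .distance import DistanceVector
from .io_core import ExpressionMatrix

__all__ = [
    "Signature",
    "per_gene_association",
    "pool_fixed_effects",
    "build_signature",
    "signature_risk_score",
    "read_signature",
]

SIGNATURE_SIZE = 500   # enrichment-scale signature
SCORING_SIZE = 200     # genes used for the risk score


def _standardize_rows(values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Standardize each row to mean 0, sample SD (ddof=1) 1; returns (z, sd)."""
    mu = values.mean(axis=1, keepdims=True)
    sd = values.std(axis=1, ddof=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = (values - mu) / sd
    return z, sd.ravel()


def per_gene_association(
    expr: ExpressionMatrix, distances: DistanceVector, cohort_label: str
) -> pd.DataFrame:
    """Regress the distance on each gene's standardized expression.

    Returns a frame with columns gene_id, cohort, beta, se, n. Zero-variance
    genes are excluded (they carry no information and their slope is
    undefined).
    """
    if expr.sample_ids != distances.sample_ids:
        raise ValueError("expression and distance vector must cover the same samples in order")
    n = expr.n_samples
    if n < 4:
        raise ValueError(f"per-gene regression requires >= 4 samples, got {n}")
    z, sd = _standardize_rows(expr.values)
    keep = sd > 0
    if not keep.any():
        raise ValueError("all genes have zero variance")
    z = z[keep]
    genes = [g for g, k in zip(expr.gene_ids, keep) if k]
    d = np.asarray(distances.distances, dtype=float)
    dc = d - d.mean()
    sxx = float(n - 1)  # standardized rows: sum of squares is n - 1
    beta = (z @ dc) / sxx
    rss = np.sum(dc**2) - beta**2 * sxx
    rss = np.maximum(rss, 0.0)
    se = np.sqrt(rss / (n - 2) / sxx)
    return pd.DataFrame(
        {"gene_id": genes, "cohort": cohort_label, "beta": beta, "se": se, "n": n}
    )


def pool_fixed_effects(associations, strict: bool = True) -> pd.DataFrame:
    """Inverse-variance fixed-effects pooling of per-cohort gene slopes.

    ``associations`` is an iterable of per-cohort frames from
    :func:`per_gene_association`. With ``strict=True`` only genes present in
    every cohort are pooled (a gene dropped for zero variance in any cohort is
    excluded). Returns gene_id, pooled_beta, pooled_se, z, n_cohorts.
    """
    frames = [a for a in associations]
    if not frames:
        raise ValueError("no association tables given")
    combined = pd.concat(frames, ignore_index=True)
    if (combined["se"] <= 0).any():
        bad = combined.loc[combined["se"] <= 0, "gene_id"].iloc[0]
        raise ValueError(f"non-positive standard error for gene {bad!r}")
    n_cohorts = combined["cohort"].nunique()
    counts = combined.groupby("gene_id")["cohort"].nunique()
    if strict:
        keep = counts[counts == n_cohorts].index
        combined = combined[combined["gene_id"].isin(keep)]
        if combined.empty:
            raise ValueError("no gene is present in every cohort")
    w = 1.0 / combined["se"] ** 2
    combined = combined.assign(_w=w, _wb=w * combined["beta"])
    g = combined.groupby("gene_id", sort=True)
    sw = g["_w"].sum()
    pooled_beta = g["_wb"].sum() / sw
    pooled_se = 1.0 / np.sqrt(sw)
    out = pd.DataFrame(
        {
            "gene_id": sw.index,
            "pooled_beta": pooled_beta.to_numpy(),
            "pooled_se": pooled_se.to_numpy(),
            "n_cohorts": g.size().to_numpy(),
        }
    ).reset_index(drop=True)
    out["z"] = out["pooled_beta"] / out["pooled_se"]
    return out


@dataclass
class Signature:
    """Ranked gene list with pooled meta-analysis coefficients as weights."""

    entries: pd.DataFrame  # columns: gene_id, pooled_beta, pooled_se, z, rank
    reference_label: str

    def __post_init__(self) -> None:
        if self.entries["gene_id"].duplicated().any():
            raise ValueError("signature contains duplicate genes")

    @property
    def size(self) -> int:
        return len(self.entries)

    def write(self, path) -> None:
        self.entries.to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_signature(path, reference_label: str = "") -> Signature:
    df = pd.read_csv(path, sep="\t")
    required = {"gene_id", "pooled_beta", "pooled_se", "z", "rank"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"signature file {path} is missing column(s) {sorted(missing)}")
    return Signature(df, reference_label)


def build_signature(pooled: pd.DataFrame, k: int, reference_label: str,
                    rank_by: str = "z") -> Signature:
    """Top-k genes by meta-analytic association strength.

    ``rank_by="z"`` ranks by |z| (default); ``rank_by="beta"`` by |pooled_beta|.
    Ties break by the other statistic's magnitude, then gene id.
    """
    if k > len(pooled):
        raise ValueError(f"requested {k} genes but only {len(pooled)} are pooled")
    if rank_by not in ("z", "beta"):
        raise ValueError(f"rank_by must be 'z' or 'beta', got {rank_by!r}")
    df = pooled.copy()
    df["_az"] = df["z"].abs()
    df["_ab"] = df["pooled_beta"].abs()
    keys = ["_az", "_ab"] if rank_by == "z" else ["_ab", "_az"]
    df = df.sort_values(by=keys + ["gene_id"], ascending=[False, False, True], kind="stable")
    df = df.head(k).drop(columns=["_az", "_ab"]).reset_index(drop=True)
    df["rank"] = np.arange(1, k + 1)
    cols = ["gene_id", "pooled_beta", "pooled_se", "z", "rank"]
    extra = [c for c in df.columns if c not in cols]
    return Signature(df[cols + extra], reference_label)


def signature_risk_score(expr: ExpressionMatrix, sig: Signature,
                         top_k: int = SCORING_SIZE) -> np.ndarray:
    """Weighted risk score over the top signature genes.

    score_j = sum over the top_k signature genes present in ``expr`` of
    pooled_beta_g * standardized expression of g in sample j (standardization
    within the scored cohort). Signature genes missing from the cohort, or
    constant in it, are dropped with a warning; no overlap is an error.

    The score tracks the stem-cell *distance*: a high score means far from
    stem cells, i.e. *low* risk of death.
    """
    entries = sig.entries.head(top_k)
    expr_genes = set(expr.gene_ids)
    present = entries[entries["gene_id"].isin(expr_genes)]
    dropped = len(entries) - len(present)
    if len(present) == 0:
        raise ValueError("no signature gene is present in the expression matrix")
    if dropped:
        warnings.warn(f"{dropped} signature gene(s) absent from cohort were dropped", stacklevel=2)
    sub = expr.subset_genes(list(present["gene_id"]))
    z, sd = _standardize_rows(sub.values)
    usable = sd > 0
    if not usable.any():
        raise ValueError("all signature genes are constant in the scored cohort")
    if not usable.all():
        warnings.warn(
            f"{int((~usable).sum())} signature gene(s) constant in cohort were dropped",
            stacklevel=2,
        )
    weights = present["pooled_beta"].to_numpy()[usable]
    return weights @ z[usable]
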