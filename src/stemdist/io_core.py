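"""Tabular I/O and cohort assembly.

All expression data are genes-in-rows, tab-delimited text: first column is the
gene (or probe-set) identifier, the header row carries sample identifiers, and
the body is numeric log2-scale expression. Clinical tables are tab-delimited
with mandatory columns ``sample``, ``time`` (months, > 0) and ``event``
(1 = death/event, 0 = censored); any further columns are kept as covariates.

One strict dialect only: missing or non-finite values are rejected, never
imputed, and duplicate identifiers are hard errors. Everything downstream
assumes log2 scale; linear-scale input must be declared with
``transform="log2"`` which applies x -> log2(x + 1).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger("stemdist")

__all__ = [
    "ExpressionMatrix",
    "ClinicalTable",
    "Cohort",
    "read_expression_matrix",
    "write_expression_matrix",
    "read_clinical_table",
    "write_clinical_table",
    "align_cohort",
]


def _check_unique(ids, what: str) -> None:
    seen: set = set()
    dups = []
    for x in ids:
        if x in seen:
            dups.append(x)
        seen.add(x)
    if dups:
        raise ValueError(f"duplicate {what} id(s): {sorted(set(map(str, dups)))}")


@dataclass
class ExpressionMatrix:
    """Log2-scale expression, genes x samples."""

    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.values = np.asarray(self.values, dtype=float)
        _check_unique(self.gene_ids, "gene")
        _check_unique(self.sample_ids, "sample")
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        if not np.all(np.isfinite(self.values)):
            r, c = np.argwhere(~np.isfinite(self.values))[0]
            raise ValueError(
                f"non-finite expression value at gene {self.gene_ids[r]!r}, "
                f"sample {self.sample_ids[c]!r}"
            )

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ExpressionMatrix":
        return cls(list(df.index), list(df.columns), df.to_numpy(dtype=float))

    def subset_genes(self, gene_ids) -> "ExpressionMatrix":
        """Restrict to the given genes, in the given order."""
        index = {g: i for i, g in enumerate(self.gene_ids)}
        missing = [g for g in gene_ids if g not in index]
        if missing:
            raise KeyError(f"gene id(s) not in matrix: {missing[:10]}")
        rows = [index[g] for g in gene_ids]
        return ExpressionMatrix(list(gene_ids), list(self.sample_ids), self.values[rows])

    def subset_samples(self, sample_ids) -> "ExpressionMatrix":
        index = {s: i for i, s in enumerate(self.sample_ids)}
        missing = [s for s in sample_ids if s not in index]
        if missing:
            raise KeyError(f"sample id(s) not in matrix: {missing[:10]}")
        cols = [index[s] for s in sample_ids]
        return ExpressionMatrix(list(self.gene_ids), list(sample_ids), self.values[:, cols])


@dataclass
class ClinicalTable:
    """Per-sample survival data: time in months (> 0), binary event flag."""

    sample_ids: list[str]
    time: np.ndarray
    event: np.ndarray
    covariates: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.time = np.asarray(self.time, dtype=float)
        self.event = np.asarray(self.event)
        _check_unique(self.sample_ids, "sample")
        n = len(self.sample_ids)
        if self.time.shape != (n,) or self.event.shape != (n,):
            raise ValueError("time/event length does not match sample count")
        if not np.all(np.isfinite(self.time)) or np.any(self.time <= 0):
            raise ValueError("survival time must be finite and strictly positive")
        if not np.all(np.isin(self.event, [0, 1])):
            bad = self.event[~np.isin(self.event, [0, 1])][0]
            raise ValueError(f"event indicator must be 0 or 1, got {bad!r}")
        self.event = self.event.astype(int)
        if self.covariates is not None:
            if list(self.covariates.index) != self.sample_ids:
                self.covariates = self.covariates.loc[self.sample_ids]

    @property
    def n(self) -> int:
        return len(self.sample_ids)

    @property
    def n_events(self) -> int:
        return int(self.event.sum())

    def subset(self, sample_ids) -> "ClinicalTable":
        index = {s: i for i, s in enumerate(self.sample_ids)}
        missing = [s for s in sample_ids if s not in index]
        if missing:
            raise KeyError(f"sample id(s) not in clinical table: {missing[:10]}")
        rows = [index[s] for s in sample_ids]
        cov = None
        if self.covariates is not None:
            cov = self.covariates.iloc[rows].copy()
        return ClinicalTable(list(sample_ids), self.time[rows], self.event[rows], cov)


@dataclass
class Cohort:
    """Expression and clinical data over an identical, identically ordered sample set."""

    expression: ExpressionMatrix
    clinical: ClinicalTable
    name: str = "cohort"

    def __post_init__(self) -> None:
        if self.expression.sample_ids != self.clinical.sample_ids:
            raise ValueError(
                "expression and clinical sample ids differ; use align_cohort()"
            )

    @property
    def sample_ids(self) -> list[str]:
        return self.expression.sample_ids


def read_expression_matrix(path, transform: str = "none") -> ExpressionMatrix:
    """Read a genes-in-rows expression TSV.

    Parameters
    ----------
    path : path-like
        Tab-delimited file; first column gene id, header row sample ids.
    transform : {"none", "log2"}
        ``log2`` declares linear-scale non-negative input and applies
        ``log2(x + 1)``.
    """
    if transform not in ("none", "log2"):
        raise ValueError(f"unknown transform {transform!r}")
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    if df.index.has_duplicates:
        dups = sorted(set(df.index[df.index.duplicated()]))
        raise ValueError(f"duplicate gene id(s) in {path}: {dups}")
    if df.columns.has_duplicates:
        dups = sorted(set(df.columns[df.columns.duplicated()]))
        raise ValueError(f"duplicate sample id(s) in {path}: {dups}")
    try:
        num = df.apply(pd.to_numeric, errors="raise")
    except (ValueError, TypeError):
        num_coerced = df.apply(pd.to_numeric, errors="coerce")
        r, c = np.argwhere(num_coerced.isna().to_numpy())[0]
        raise ValueError(
            f"non-numeric expression value at gene {df.index[r]!r}, "
            f"sample {df.columns[c]!r} in {path}"
        ) from None
    values = num.to_numpy(dtype=float)
    if transform == "log2":
        if np.any(values < 0):
            r, c = np.argwhere(values < 0)[0]
            raise ValueError(
                f"negative value at gene {df.index[r]!r}, sample {df.columns[c]!r}: "
                "log2 transform requires non-negative linear-scale input"
            )
        values = np.log2(values + 1.0)
    return ExpressionMatrix(list(df.index), list(df.columns), values)


def write_expression_matrix(expr: ExpressionMatrix, path) -> None:
    df = expr.to_frame()
    df.index.name = "gene"
    df.to_csv(path, sep="\t", float_format="%.17g")


def read_clinical_table(path) -> ClinicalTable:
    """Read a clinical TSV with mandatory columns sample, time, event."""
    df = pd.read_csv(path, sep="\t")
    for col in ("sample", "time", "event"):
        if col not in df.columns:
            raise ValueError(f"clinical table {path} is missing mandatory column {col!r}")
    sample_ids = [str(s) for s in df["sample"]]
    extra = [c for c in df.columns if c not in ("sample", "time", "event")]
    cov = None
    if extra:
        cov = df[extra].copy()
        cov.index = pd.Index(sample_ids)
    return ClinicalTable(sample_ids, df["time"].to_numpy(), df["event"].to_numpy(), cov)


def write_clinical_table(clinical: ClinicalTable, path) -> None:
    df = pd.DataFrame(
        {"sample": clinical.sample_ids, "time": clinical.time, "event": clinical.event}
    )
    if clinical.covariates is not None:
        for col in clinical.covariates.columns:
            df[col] = clinical.covariates[col].to_numpy()
    df.to_csv(path, sep="\t", index=False, float_format="%.17g")


def align_cohort(expr: ExpressionMatrix, clinical: ClinicalTable, name: str = "cohort") -> Cohort:
    """Restrict both components to their common samples, in expression order.

    Samples present in only one component are dropped (and logged); an empty
    intersection is an error.
    """
    clin_set = set(clinical.sample_ids)
    common = [s for s in expr.sample_ids if s in clin_set]
    if not common:
        raise ValueError("expression and clinical tables share no sample ids")
    dropped_expr = [s for s in expr.sample_ids if s not in clin_set]
    expr_set = set(expr.sample_ids)
    dropped_clin = [s for s in clinical.sample_ids if s not in expr_set]
    if dropped_expr:
        logger.info("align_cohort(%s): dropped %d expression-only samples", name, len(dropped_expr))
    if dropped_clin:
        logger.info("align_cohort(%s): dropped %d clinical-only samples", name, len(dropped_clin))
    return Cohort(expr.subset_samples(common), clinical.subset(common), name)
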