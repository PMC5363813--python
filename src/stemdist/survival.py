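"""Survival-side statistics.

The distance (or any risk score) is evaluated against survival with a
univariate Cox proportional-hazards model. Model quality is summarized by the
Gonen-Heller concordance probability estimate (CPE): for a fitted coefficient
beta and linear predictors eta_i = beta * score_i, each unordered sample pair
contributes

    1 / (1 + exp(-|eta_i - eta_j|))

and the CPE is the mean over pairs. This is a model-based estimator — it never
touches the censoring times — so it is usable on held-out folds from the
training-fold coefficient alone. 0.5 is a random model (and the value at
beta = 0 exactly), 1.0 a perfect one. A brute-force Harrell's C over
censoring-comparable pairs serves as the independent empirical oracle.

The Cox partial likelihood is maximized by a dedicated Newton solver with the
Efron approximation for tied event times. Risk scores from different
predictors are made comparable by centering to mean 0 and scaling to IQR 1,
and continuous predictors are stratified into low/medium/high groups at the
tertile boundaries (or at externally supplied, training-derived cutpoints).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import norm

from .io_core import ClinicalTable

__all__ = [
    "CoxFit",
    "RiskGroups",
    "fit_cox_univariate",
    "concordance_cpe",
    "cpe_from_linear_predictor",
    "concordance_oracle",
    "normalize_risk_scores",
    "stratify_tertiles",
    "logrank_test",
]


@dataclass
class CoxFit:
    """Univariate proportional-hazards fit summary."""

    coefficient: float
    se: float
    hazard_ratio: float
    ci_low: float
    ci_high: float
    p_value: float
    n: int
    n_events: int

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "CoxFit":
        with open(path) as fh:
            return cls(**json.load(fh))


def _efron_quantities(beta: float, x: np.ndarray, time: np.ndarray, event: np.ndarray):
    """Log partial likelihood, gradient and (positive) information at beta.

    Efron's approximation for tied event times. Inputs need not be sorted.
    Fully vectorized: risk-set sums via cumulative sums over samples sorted by
    descending time, Efron's within-tie corrections via per-tie-group event
    sums expanded over the l = 0..d-1 terms.
    """
    order = np.argsort(-time, kind="stable")
    t = time[order]
    xs = x[order]
    es = event[order].astype(bool)
    eta = beta * xs
    # guard against overflow: the partial likelihood is invariant to shifting eta
    eta = eta - eta.max()
    w = np.exp(eta)
    cum0 = np.cumsum(w)
    cum1 = np.cumsum(w * xs)
    cum2 = np.cumsum(w * xs * xs)

    starts = np.flatnonzero(np.r_[True, t[1:] != t[:-1]])
    ends = np.r_[starts[1:], t.size]
    d = np.add.reduceat(es.astype(float), starts)
    has_event = d > 0
    starts_e = starts[has_event]
    ends_e = ends[has_event]
    d_e = d[has_event].astype(int)
    if d_e.size == 0:
        raise ValueError("no events in the data")

    S0 = cum0[ends_e - 1]
    S1 = cum1[ends_e - 1]
    S2 = cum2[ends_e - 1]
    ew = np.where(es, w, 0.0)
    D0 = np.add.reduceat(ew, starts)[has_event]
    D1 = np.add.reduceat(ew * xs, starts)[has_event]
    D2 = np.add.reduceat(ew * xs * xs, starts)[has_event]

    # expand each tie group with d events into its l = 0..d-1 Efron terms
    reps = d_e
    total = int(reps.sum())
    grp = np.repeat(np.arange(reps.size), reps)
    offsets = np.repeat(np.cumsum(reps) - reps, reps)
    l = np.arange(total) - offsets
    frac = l / reps[grp]
    denom = S0[grp] - frac * D0[grp]
    num1 = S1[grp] - frac * D1[grp]
    num2 = S2[grp] - frac * D2[grp]

    x_events_sum = float(np.sum(xs[es]))
    eta_events_sum = float(np.sum(eta[es]))
    xbar = num1 / denom
    loglik = eta_events_sum - float(np.sum(np.log(denom)))
    grad = x_events_sum - float(np.sum(xbar))
    info = float(np.sum(num2 / denom - xbar**2))
    return loglik, grad, info


def _newton_cox(x: np.ndarray, time: np.ndarray, event: np.ndarray,
                max_iter: int = 60, tol: float = 1e-10) -> tuple[float, float]:
    """Maximize the univariate Efron partial likelihood; returns (beta, se)."""
    xc = x - x.mean()  # centering leaves beta unchanged, improves conditioning
    beta = 0.0
    ll, grad, info = _efron_quantities(beta, xc, time, event)
    for _ in range(max_iter):
        if info <= 0:
            raise ValueError("non-positive information; degenerate risk variable")
        step = grad / info
        # damped Newton: halve until the partial likelihood does not decrease
        for _ in range(30):
            cand = beta + step
            ll_new, grad_new, info_new = _efron_quantities(cand, xc, time, event)
            if ll_new >= ll - 1e-12:
                break
            step *= 0.5
        beta, ll, grad, info = cand, ll_new, grad_new, info_new
        if abs(step) < tol * (1.0 + abs(beta)):
            break
    return float(beta), float(1.0 / np.sqrt(info))


def _as_scores(scores) -> np.ndarray:
    a = np.asarray(scores, dtype=float)
    if a.ndim != 1:
        raise ValueError("scores must be a 1-D vector")
    if not np.all(np.isfinite(a)):
        raise ValueError("scores contain non-finite values")
    return a


def fit_cox_univariate(scores, clinical: ClinicalTable) -> CoxFit:
    """Fit time ~ scores with a univariate Cox proportional-hazards model.

    Efron approximation for tied event times; Wald standard error, 95% CI on
    the hazard ratio and two-sided Wald p-value.
    """
    s = _as_scores(scores)
    if s.size != clinical.n:
        raise ValueError("scores and clinical table have different lengths")
    if clinical.n_events < 2:
        raise ValueError(f"need >= 2 events, got {clinical.n_events}")
    if np.ptp(s) == 0:
        raise ValueError("risk scores are constant; coefficient not identifiable")
    beta, se = _newton_cox(s, clinical.time, clinical.event)
    z975 = norm.ppf(0.975)
    hr = float(np.exp(beta))
    zstat = beta / se
    return CoxFit(
        coefficient=beta,
        se=se,
        hazard_ratio=hr,
        ci_low=float(np.exp(beta - z975 * se)),
        ci_high=float(np.exp(beta + z975 * se)),
        p_value=float(2.0 * norm.sf(abs(zstat))),
        n=clinical.n,
        n_events=clinical.n_events,
    )


def cpe_from_linear_predictor(eta) -> float:
    """Gonen-Heller CPE from linear-predictor values (beta * score).

    Mean over unordered pairs of 1 / (1 + exp(-|eta_i - eta_j|)); tied linear
    predictors contribute 0.5, so an all-zero predictor (beta = 0) returns 0.5.
    """
    eta = np.asarray(eta, dtype=float)
    if eta.size < 2:
        raise ValueError("CPE requires at least 2 samples")
    diffs = np.abs(eta[:, None] - eta[None, :])
    iu = np.triu_indices(eta.size, k=1)
    return float(np.mean(expit(diffs[iu])))


def concordance_cpe(fit: CoxFit, scores) -> float:
    """CPE of a fitted univariate model evaluated on the given risk scores.

    Model-based: uses only the fitted coefficient and the scores, never the
    censoring times, so it can score held-out samples.
    """
    s = _as_scores(scores)
    if not np.isfinite(fit.coefficient):
        raise ValueError("fitted coefficient is not finite")
    return cpe_from_linear_predictor(fit.coefficient * s)


def concordance_oracle(scores, clinical: ClinicalTable) -> float:
    """Harrell's C by brute-force pair enumeration.

    A pair is comparable when the shorter observed time is an event and the
    times differ. Among comparable pairs, the pair is concordant when the
    earlier-failing sample has the higher score; score ties count 0.5.
    """
    s = _as_scores(scores)
    if s.size != clinical.n:
        raise ValueError("scores and clinical table have different lengths")
    t = clinical.time
    e = clinical.event.astype(bool)
    # pair (i, j): i fails first (t_i < t_j, event_i)
    earlier = (t[:, None] < t[None, :]) & e[:, None]
    higher = s[:, None] > s[None, :]
    tied = s[:, None] == s[None, :]
    n_comparable = int(earlier.sum())
    if n_comparable == 0:
        raise ValueError("no comparable pairs under censoring")
    concordant = float(np.sum(earlier & higher)) + 0.5 * float(np.sum(earlier & tied))
    return concordant / n_comparable


def normalize_risk_scores(scores) -> np.ndarray:
    """Center to mean 0.0 and scale to IQR 1.0 (idempotent, affine-invariant)."""
    s = _as_scores(scores)
    if s.size < 4:
        raise ValueError("risk-score normalization requires >= 4 samples")
    q75, q25 = np.percentile(s, [75, 25])
    iqr = q75 - q25
    if iqr <= 0:
        raise ValueError("risk scores have zero IQR; cannot normalize")
    return (s - s.mean()) / iqr


@dataclass
class RiskGroups:
    """Low/medium/high risk assignment with the cutpoints that produced it."""

    sample_ids: list[str]
    group: list[str]
    cutpoints: tuple[float, float]

    def __post_init__(self) -> None:
        lo, hi = self.cutpoints
        if not lo <= hi:
            raise ValueError(f"cutpoints must be ordered, got {self.cutpoints}")
        bad = [g for g in self.group if g not in ("low", "medium", "high")]
        if bad:
            raise ValueError(f"invalid group label(s): {sorted(set(bad))}")

    def to_frame(self, scores=None) -> pd.DataFrame:
        df = pd.DataFrame({"sample": self.sample_ids, "group": self.group})
        if scores is not None:
            df.insert(1, "score", np.asarray(scores, dtype=float))
        return df

    def counts(self) -> dict[str, int]:
        return {g: self.group.count(g) for g in ("low", "medium", "high")}


def stratify_tertiles(scores, sample_ids=None, cutpoints=None) -> RiskGroups:
    """Trisect samples into low/medium/high risk groups.

    Without ``cutpoints``, thresholds are the 1/3 and 2/3 score quantiles
    (linear interpolation) and group sizes differ by at most one; with
    training-derived cutpoints, assignment is by threshold comparison
    regardless of balance. A sample exactly at a threshold goes to the lower
    group.
    """
    s = _as_scores(scores)
    if s.size < 3 and cutpoints is None:
        raise ValueError("tertile stratification requires >= 3 samples")
    if sample_ids is None:
        sample_ids = [f"s{i}" for i in range(s.size)]
    if len(sample_ids) != s.size:
        raise ValueError("sample_ids and scores have different lengths")
    if cutpoints is None:
        lo, hi = np.percentile(s, [100.0 / 3.0, 200.0 / 3.0])
    else:
        lo, hi = float(cutpoints[0]), float(cutpoints[1])
        if not lo <= hi:
            raise ValueError(f"cutpoints must be ordered, got {cutpoints!r}")
    group = ["low" if v <= lo else ("medium" if v <= hi else "high") for v in s]
    return RiskGroups(list(sample_ids), group, (float(lo), float(hi)))


def logrank_test(groups: RiskGroups, clinical: ClinicalTable):
    """K-group log-rank test; returns (chi-square statistic, p-value).

    The p-value comes from a chi-square distribution with k - 1 degrees of
    freedom, k the number of non-empty groups.
    """
    from lifelines.statistics import multivariate_logrank_test

    if set(groups.sample_ids) != set(clinical.sample_ids):
        raise ValueError("risk groups and clinical table cover different samples")
    clin = clinical.subset(groups.sample_ids)
    labels = np.asarray(groups.group)
    nonempty = [g for g in ("low", "medium", "high") if (labels == g).any()]
    if len(nonempty) < 2:
        raise ValueError("log-rank test requires >= 2 non-empty groups")
    if clin.n_events < 1:
        raise ValueError("log-rank test requires >= 1 event")
    res = multivariate_logrank_test(clin.time, labels, clin.event)
    return float(res.test_statistic), float(res.p_value)
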