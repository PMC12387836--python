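"""Cohort statistics: response-group split, summaries, t-tests, deviations.

The analysis mirrors a standard two-group surgical-outcome workup: patients
are split by whether measured postoperative FEV1 rose above the
preoperative baseline, groups are summarised as mean (SD), compared with an
unpaired pooled-variance (Student) t-test, and measured values are set
against model predictions as absolute deviations (FEV1 in mL).  A
least-squares line of postoperative on preoperative values, together with
the line of no change, characterises the cohort-level pre/post relationship.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, RegressorMixin

from .hu_volumetrics import ResectionSimulation

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class PatientRecord:
    """Demographic, spirometric, diffusion and surgical fields for one patient.

    Lung-function units: FEV1/FVC/RV in liters, DLCO in mmol/(min*kPa),
    ``*_pct`` fields in percent of predicted, ``fev1_fvc`` on the 0-1 scale.
    """

    id: str
    age: float
    sex: str
    bmi: float
    segments_removed: int
    resected_segment_labels: tuple[str, ...] = ()
    preop_fev1_l: float = np.nan
    preop_fev1_pct: float = np.nan
    preop_fev1_fvc: float = np.nan
    preop_dlco: float = np.nan
    preop_dlco_pct: float = np.nan
    preop_rv_l: float = np.nan
    preop_rv_pct: float = np.nan
    postop_fev1_l: float = np.nan
    postop_fev1_pct: float = np.nan
    postop_dlco: float = np.nan
    postop_dlco_pct: float = np.nan
    postop_rv_l: float = np.nan
    postop_rv_pct: float = np.nan
    volumetrics: ResectionSimulation | None = None

    def __post_init__(self) -> None:
        if self.segments_removed < 1:
            raise ValueError("operated patients must have segments_removed >= 1")
        if np.isfinite(self.preop_fev1_fvc) and not (0 < self.preop_fev1_fvc <= 1):
            raise ValueError("fev1_fvc must lie in (0, 1]")
        for name in ("preop_fev1_l", "preop_dlco", "preop_rv_l",
                     "postop_fev1_l", "postop_dlco", "postop_rv_l"):
            v = getattr(self, name)
            if np.isfinite(v) and v < 0:
                raise ValueError(f"{name} must be non-negative")


@dataclass(frozen=True)
class CohortSummary:
    group: str
    n: int
    stats: dict[str, tuple[float, float]]  # variable -> (mean, sample SD)


@dataclass(frozen=True)
class GroupComparison:
    """Pooled-variance two-sample t-test result for one variable."""

    variable: str
    mean_a: float
    sd_a: float
    n_a: int
    mean_b: float
    sd_b: float
    n_b: int
    t_statistic: float
    df: int
    p_value: float
    alpha: float = 0.05

    @property
    def significant(self) -> bool:
        return self.p_value < self.alpha


def cohort_to_frame(cohort: Iterable[PatientRecord]) -> pd.DataFrame:
    """Flatten patient records to one row per patient."""
    rows = []
    for p in cohort:
        row = {k: v for k, v in vars(p).items()
               if k not in ("volumetrics", "resected_segment_labels")}
        row["resected_segment_labels"] = "+".join(p.resected_segment_labels)
        if p.volumetrics is not None:
            for f in ("removed_total_fraction", "removed_functional_fraction",
                      "healthy_over_total", "ipsi_remaining_healthy_over_total",
                      "removed_healthy_over_removed_total"):
                row[f] = getattr(p.volumetrics, f)
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def split_by_response(cohort: Sequence[PatientRecord], *, ties_increase: bool = False,
                      ) -> tuple[list[PatientRecord], list[PatientRecord]]:
    """Split a cohort by postoperative FEV1 response.

    A patient is a responder (increase group) iff postoperative FEV1 (L) is
    strictly greater than preoperative; ties go to the decrease group unless
    ``ties_increase`` is set.  Patients with a missing pre- or postoperative
    value are excluded with a warning.  The two groups partition the retained
    cohort.
    """
    increase: list[PatientRecord] = []
    decrease: list[PatientRecord] = []
    for p in cohort:
        if not (np.isfinite(p.preop_fev1_l) and np.isfinite(p.postop_fev1_l)):
            logger.warning("patient %s missing pre/post FEV1; excluded from split", p.id)
            continue
        if p.postop_fev1_l > p.preop_fev1_l:
            increase.append(p)
        elif p.postop_fev1_l == p.preop_fev1_l and ties_increase:
            increase.append(p)
        else:
            decrease.append(p)
    return increase, decrease


def summarize(group: Sequence[PatientRecord] | pd.DataFrame,
              variables: Sequence[str], label: str = "") -> CohortSummary:
    """Mean and sample SD (n-1 denominator) per variable; requires n >= 2."""
    frame = group if isinstance(group, pd.DataFrame) else cohort_to_frame(group)
    if len(frame) < 2:
        raise ValueError("sample SD undefined for n < 2")
    out = {}
    for var in variables:
        x = np.asarray(frame[var], dtype=float)
        out[var] = (float(np.mean(x)), float(np.std(x, ddof=1)))
    return CohortSummary(group=label, n=len(frame), stats=out)


def pooled_t_test(a: np.ndarray, b: np.ndarray) -> tuple[float, int, float]:
    """Closed-form equal-variance two-sample t-test (two-sided).

    Returns (t, df, p).  Degenerate pooled variance: equal means give t=0,
    p=1; unequal means give an infinite-t guard with p=0 and a warning.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    n1, n2 = len(a), len(b)
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs n >= 2")
    df = n1 + n2 - 2
    sp2 = ((n1 - 1) * np.var(a, ddof=1) + (n2 - 1) * np.var(b, ddof=1)) / df
    diff = np.mean(a) - np.mean(b)
    if sp2 == 0:
        if diff == 0:
            return 0.0, df, 1.0
        warnings.warn("zero pooled variance with unequal means; p set to 0", stacklevel=2)
        return float(np.sign(diff) * np.inf), df, 0.0
    t = diff / np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    p = 2.0 * stats.t.sf(abs(t), df)
    return float(t), df, float(min(p, 1.0))


def compare_groups(a: Sequence[PatientRecord] | pd.DataFrame,
                   b: Sequence[PatientRecord] | pd.DataFrame,
                   variable: str, alpha: float = 0.05) -> GroupComparison:
    """Unpaired Student (pooled-variance) t-test between two patient groups."""
    fa = a if isinstance(a, pd.DataFrame) else cohort_to_frame(a)
    fb = b if isinstance(b, pd.DataFrame) else cohort_to_frame(b)
    xa = np.asarray(fa[variable], dtype=float)
    xb = np.asarray(fb[variable], dtype=float)
    t, df, p = pooled_t_test(xa, xb)
    return GroupComparison(
        variable=variable,
        mean_a=float(np.mean(xa)), sd_a=float(np.std(xa, ddof=1)), n_a=len(xa),
        mean_b=float(np.mean(xb)), sd_b=float(np.std(xb, ddof=1)), n_b=len(xb),
        t_statistic=t, df=df, p_value=p, alpha=alpha)


def model_deviation(measured_mean: float, predicted_mean: float,
                    as_ml: bool = False) -> float:
    """Measured minus predicted.

    With ``as_ml`` the inputs are liters and the difference is returned in
    mL rounded to the nearest 10 mL (report precision); otherwise the raw
    difference in the inputs' units.
    """
    diff = measured_mean - predicted_mean
    if as_ml:
        return float(round(diff * 1000.0, -1))
    return float(diff)


class PrePostLine(RegressorMixin, BaseEstimator):
    """Ordinary least-squares line of postoperative on preoperative values.

    Fitted attributes: ``slope_``, ``intercept_``; ``identity_residuals_``
    are the per-patient postop - preop differences (distance from the line
    of no change).
    """

    def fit(self, X, y):
        x = np.asarray(X, dtype=float).reshape(-1)
        y = np.asarray(y, dtype=float).reshape(-1)
        if len(x) < 3:
            raise ValueError("need at least 3 patients to fit a line")
        if np.var(x) == 0:
            raise ValueError("preoperative values have zero variance")
        res = stats.linregress(x, y)
        self.slope_ = float(res.slope)
        self.intercept_ = float(res.intercept)
        self.rvalue_ = float(res.rvalue)
        self.identity_residuals_ = y - x
        self.n_features_in_ = 1
        return self

    def predict(self, X):
        x = np.asarray(X, dtype=float).reshape(-1)
        return self.slope_ * x + self.intercept_


def fit_pre_post_line(cohort: Sequence[PatientRecord] | pd.DataFrame,
                      variable: str = "fev1_l",
                      ) -> tuple[float, float, np.ndarray]:
    """OLS fit of ``postop_<variable>`` on ``preop_<variable>``.

    Returns (slope, intercept, identity-line residuals postop - preop).
    """
    frame = cohort if isinstance(cohort, pd.DataFrame) else cohort_to_frame(cohort)
    pre = np.asarray(frame[f"preop_{variable}"], dtype=float)
    post = np.asarray(frame[f"postop_{variable}"], dtype=float)
    line = PrePostLine().fit(pre, post)
    return line.slope_, line.intercept_, line.identity_residuals_


def comparison_report(comparisons: Iterable[GroupComparison]) -> pd.DataFrame:
    """Tabular report: one row per compared variable."""
    return pd.DataFrame([{
        "variable": c.variable,
        "mean_increase": c.mean_a, "sd_increase": c.sd_a, "n_increase": c.n_a,
        "mean_decrease": c.mean_b, "sd_decrease": c.sd_b, "n_decrease": c.n_b,
        "t": c.t_statistic, "df": c.df, "p": c.p_value,
        "significant": c.significant,
    } for c in comparisons])
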