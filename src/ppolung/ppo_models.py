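"""Predicted postoperative lung function (ppoFEV1 / ppoDLCO).

Three predictors are implemented:

* the segment-counting "5% rule" — each of the ~20 bronchopulmonary segments
  is assumed to carry 5% of total function, so
  ``ppo = preop * (1 - 0.05 * segments_removed)``;
* the Brunelli linear regressions for percentage FEV1 and DLCO loss, driven
  by age, the percentage of removed *functioning* parenchyma, the Korst COPD
  index (FEV1 %predicted as a fraction plus FEV1/FVC) and, for DLCO, the
  obstruction ratio and the measured DLCO;
* a volumetric model that scales the preoperative value by the fraction of
  functional (well-aerated) parenchyma removed, as measured on quantitative
  CT.

All three are exposed both as scikit-learn predictor estimators operating on
patient DataFrames and as scalar/vector functions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, RegressorMixin


# ---------------------------------------------------------------------------
# coefficients
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LinearLossModel:
    """Intercept + named linear terms giving a percentage loss."""

    intercept: float
    terms: tuple[tuple[str, float], ...]

    def evaluate(self, **inputs: float) -> float:
        total = self.intercept
        for name, coef in self.terms:
            total += coef * inputs[name]
        return total


@dataclass(frozen=True)
class BrunelliCoefficients:
    """Published regression coefficients for % FEV1 and % DLCO loss.

    Defaults are fixed to the printed values; override only via explicit
    configuration (e.g. a ``brunelli:`` YAML block).
    """

    fev1: LinearLossModel = field(default_factory=lambda: LinearLossModel(
        intercept=21.34,
        terms=(("age", -0.47), ("removed_functioning_pct", 0.49), ("copd_index", 17.91)),
    ))
    dlco: LinearLossModel = field(default_factory=lambda: LinearLossModel(
        intercept=35.99,
        terms=(("age", -0.31), ("fev1_fvc", -36.47), ("dlco", 0.33),
               ("removed_functioning_pct", 0.54)),
    ))

    @classmethod
    def from_config(cls, config: dict | None) -> "BrunelliCoefficients":
        """Build coefficients from an override mapping.

        ``config`` may contain ``fev1`` / ``dlco`` sub-mappings with keys
        ``intercept`` plus term names; unspecified entries keep defaults.
        """
        base = cls()
        if not config:
            return base

        def override(model: LinearLossModel, overrides: dict) -> LinearLossModel:
            intercept = float(overrides.get("intercept", model.intercept))
            terms = tuple((name, float(overrides.get(name, coef)))
                          for name, coef in model.terms)
            unknown = set(overrides) - {"intercept"} - {n for n, _ in model.terms}
            if unknown:
                raise ValueError(f"unknown Brunelli coefficient names: {sorted(unknown)}")
            return LinearLossModel(intercept=intercept, terms=terms)

        return cls(fev1=override(base.fev1, config.get("fev1", {})),
                   dlco=override(base.dlco, config.get("dlco", {})))


DEFAULT_COEFFICIENTS = BrunelliCoefficients()


# ---------------------------------------------------------------------------
# scalar operations
# ---------------------------------------------------------------------------

def copd_index(fev1_pct_pred: float, fev1_fvc: float) -> float:
    """Korst composite obstruction index: FEV1 %predicted (fraction) + FEV1/FVC.

    Both inputs are unitless and must lie in (0, 2]; e.g. 92% predicted with
    an obstruction ratio of 0.69 gives 0.92 + 0.69 = 1.61.
    """
    fev1_pct_pred = float(fev1_pct_pred)
    fev1_fvc = float(fev1_fvc)
    for name, v in (("fev1_pct_pred", fev1_pct_pred), ("fev1_fvc", fev1_fvc)):
        if not (0.0 < v <= 2.0):
            raise ValueError(f"{name}={v} outside (0, 2]; supply fractions, not percent")
    return fev1_pct_pred + fev1_fvc


def five_percent_rule(preop_value, segments_removed, per_segment_fraction: float = 0.05):
    """Segment-counting prediction: ppo = preop * (1 - 0.05 * segments removed).

    ``segments_removed`` may be fractional (cohort means).  More than
    1/per_segment_fraction segments would imply negative function and is
    rejected.
    """
    preop_value = np.asarray(preop_value, dtype=float)
    segments_removed = np.asarray(segments_removed, dtype=float)
    loss = per_segment_fraction * segments_removed
    if np.any(segments_removed < 0) or np.any(loss > 1.0):
        raise ValueError("segments_removed must satisfy 0 <= 0.05 * n <= 1")
    out = preop_value * (1.0 - loss)
    return float(out) if out.ndim == 0 else out


def brunelli_fev1_loss(age, removed_functioning_pct, copd_index,
                       coefficients: BrunelliCoefficients = DEFAULT_COEFFICIENTS):
    """Predicted % FEV1 loss from the Brunelli regression (unclamped).

    ``removed_functioning_pct`` is on the 0-100 scale (16.42 means 16.42%).
    A negative result is a predicted functional gain and is returned as-is.
    """
    age = np.asarray(age, dtype=float)
    removed = np.asarray(removed_functioning_pct, dtype=float)
    ci = np.asarray(copd_index, dtype=float)
    if np.any(age <= 0):
        raise ValueError("age must be positive")
    if np.any((removed > 0) & (removed < 1.0)):
        raise ValueError(
            "removed_functioning_pct looks like a 0-1 fraction; supply percent (0-100 scale)")
    out = (coefficients.fev1.intercept
           + dict(coefficients.fev1.terms)["age"] * age
           + dict(coefficients.fev1.terms)["removed_functioning_pct"] * removed
           + dict(coefficients.fev1.terms)["copd_index"] * ci)
    return float(out) if out.ndim == 0 else out


def brunelli_dlco_loss(age, fev1_fvc, dlco, removed_functioning_pct,
                       coefficients: BrunelliCoefficients = DEFAULT_COEFFICIENTS):
    """Predicted % DLCO loss from the Brunelli regression (unclamped).

    ``fev1_fvc`` enters on the 0-1 scale and ``dlco`` in measured units,
    mmol/(min*kPa); percent-scale obstruction ratios are rejected with a
    unit hint.
    """
    age = np.asarray(age, dtype=float)
    ratio = np.asarray(fev1_fvc, dtype=float)
    dlco = np.asarray(dlco, dtype=float)
    removed = np.asarray(removed_functioning_pct, dtype=float)
    if np.any(age <= 0):
        raise ValueError("age must be positive")
    if np.any(ratio > 1.5):
        raise ValueError("fev1_fvc looks percent-scaled; supply the 0-1 ratio")
    if np.any((ratio <= 0) | (ratio > 1.0)):
        raise ValueError("fev1_fvc must lie in (0, 1]")
    terms = dict(coefficients.dlco.terms)
    out = (coefficients.dlco.intercept
           + terms["age"] * age
           + terms["fev1_fvc"] * ratio
           + terms["dlco"] * dlco
           + terms["removed_functioning_pct"] * removed)
    return float(out) if out.ndim == 0 else out


def apply_loss(preop_value, loss_pct):
    """ppo = preop * (1 - loss/100), clamped at zero with a warning.

    Loss percentages above 100 would extrapolate below zero function; the
    returned ppo is clamped but the loss itself is never modified.
    """
    preop_value = np.asarray(preop_value, dtype=float)
    if np.any(preop_value < 0):
        raise ValueError("preop_value must be non-negative")
    out = preop_value * (1.0 - np.asarray(loss_pct, dtype=float) / 100.0)
    if np.any(out < 0):
        warnings.warn("predicted loss exceeds 100%; ppo clamped at 0", stacklevel=2)
        out = np.maximum(out, 0.0)
    return float(out) if out.ndim == 0 else out


def volumetric_ppo(preop_value, removed_functional_fraction):
    """CT-volumetric prediction: scale preop by the removed functional fraction.

    ``removed_functional_fraction`` is the removed well-aerated volume over
    the whole-lung well-aerated volume, on the 0-1 scale.
    """
    frac = np.asarray(removed_functional_fraction, dtype=float)
    if np.any((frac < 0) | (frac > 1)):
        raise ValueError("removed_functional_fraction must lie in [0, 1]")
    out = np.asarray(preop_value, dtype=float) * (1.0 - frac)
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class PredictionResult:
    """All model predictions for one patient.

    ppo values are clamped at zero; the Brunelli loss percentages are stored
    pre-clamp (a negative loss is a predicted gain).
    """

    ppo_fev1_5pct: float
    ppo_fev1_brunelli: float
    ppo_fev1_volumetric: float | None
    ppo_dlco_5pct: float
    ppo_dlco_brunelli: float
    fev1_loss_brunelli_pct: float
    dlco_loss_brunelli_pct: float


def predict_patient(*, preop_fev1_l: float, preop_dlco: float, age: float,
                    fev1_pct_pred: float, fev1_fvc: float, segments_removed: float,
                    removed_functional_fraction: float | None = None,
                    coefficients: BrunelliCoefficients = DEFAULT_COEFFICIENTS,
                    ) -> PredictionResult:
    """Run every prediction model for one patient record.

    When no CT-derived ``removed_functional_fraction`` is available the
    Brunelli models fall back to the 5%-rule resection extent
    (5% per segment of total function) and the volumetric prediction is None.
    """
    if removed_functional_fraction is not None:
        removed_pct = removed_functional_fraction * 100.0
        ppo_fev1_vol = volumetric_ppo(preop_fev1_l, removed_functional_fraction)
    else:
        removed_pct = 5.0 * segments_removed
        ppo_fev1_vol = None
    ci = copd_index(fev1_pct_pred, fev1_fvc)
    fev1_loss = brunelli_fev1_loss(age, removed_pct, ci, coefficients)
    dlco_loss = brunelli_dlco_loss(age, fev1_fvc, preop_dlco, removed_pct, coefficients)
    return PredictionResult(
        ppo_fev1_5pct=five_percent_rule(preop_fev1_l, segments_removed),
        ppo_fev1_brunelli=apply_loss(preop_fev1_l, fev1_loss),
        ppo_fev1_volumetric=ppo_fev1_vol,
        ppo_dlco_5pct=five_percent_rule(preop_dlco, segments_removed),
        ppo_dlco_brunelli=apply_loss(preop_dlco, dlco_loss),
        fev1_loss_brunelli_pct=float(fev1_loss),
        dlco_loss_brunelli_pct=float(dlco_loss),
    )


# ---------------------------------------------------------------------------
# estimators
# ---------------------------------------------------------------------------

class _StaticPredictor(RegressorMixin, BaseEstimator):
    """Base for closed-form predictors: fit only records/validates columns."""

    _required: tuple[str, ...] = ()

    def fit(self, X: pd.DataFrame, y=None):
        self._check_columns(X)
        self.feature_names_in_ = np.asarray(list(X.columns))
        self.n_features_in_ = X.shape[1]
        return self

    def _check_columns(self, X: pd.DataFrame) -> None:
        if not isinstance(X, pd.DataFrame):
            raise TypeError(f"{type(self).__name__} expects a patient DataFrame")
        missing = [c for c in self._required if c not in X.columns]
        if missing:
            raise ValueError(f"missing required columns: {missing}")


class FivePercentRule(_StaticPredictor):
    """5%-per-segment ppo predictor over columns ``preop`` and ``segments_removed``."""

    _required = ("preop", "segments_removed")

    def __init__(self, per_segment_fraction: float = 0.05):
        self.per_segment_fraction = per_segment_fraction

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        self._check_columns(X)
        return np.asarray(five_percent_rule(
            X["preop"], X["segments_removed"], self.per_segment_fraction))


class BrunelliFEV1(_StaticPredictor):
    """Brunelli ppoFEV1 predictor.

    Requires columns ``preop_fev1_l``, ``age``, ``removed_functioning_pct``
    and ``copd_index``; ``predict_loss`` returns the unclamped % loss.
    """

    _required = ("preop_fev1_l", "age", "removed_functioning_pct", "copd_index")

    def __init__(self, coefficients: BrunelliCoefficients = DEFAULT_COEFFICIENTS):
        self.coefficients = coefficients

    def predict_loss(self, X: pd.DataFrame) -> np.ndarray:
        self._check_columns(X)
        return np.asarray(brunelli_fev1_loss(
            X["age"], X["removed_functioning_pct"], X["copd_index"], self.coefficients))

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        return np.asarray(apply_loss(X["preop_fev1_l"], self.predict_loss(X)))


class BrunelliDLCO(_StaticPredictor):
    """Brunelli ppoDLCO predictor over ``preop_dlco``, ``age``, ``fev1_fvc``,
    ``removed_functioning_pct``."""

    _required = ("preop_dlco", "age", "fev1_fvc", "removed_functioning_pct")

    def __init__(self, coefficients: BrunelliCoefficients = DEFAULT_COEFFICIENTS):
        self.coefficients = coefficients

    def predict_loss(self, X: pd.DataFrame) -> np.ndarray:
        self._check_columns(X)
        return np.asarray(brunelli_dlco_loss(
            X["age"], X["fev1_fvc"], X["preop_dlco"],
            X["removed_functioning_pct"], self.coefficients))

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        return np.asarray(apply_loss(X["preop_dlco"], self.predict_loss(X)))


class VolumetricPPO(_StaticPredictor):
    """CT-volumetric ppo predictor over ``preop`` and ``removed_functional_fraction``."""

    _required = ("preop", "removed_functional_fraction")

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        self._check_columns(X)
        return np.asarray(volumetric_ppo(X["preop"], X["removed_functional_fraction"]))
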