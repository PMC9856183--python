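"""Chemiluminescence hematocrit assay: calibration, inversion, interference.

The reader's integrated photon count (RLU) is linear in red-cell content, so
HCT is calibrated by ordinary least squares of RLU on HCT over reconstituted
standards and estimated by inverting the fitted line. The calibration is
fitted *with* an intercept: a zero blank signal is not assumed. Estimates more
than 5 HCT points outside the calibration range are flagged as extrapolation,
and negative estimates clamp to zero with a flag.

Interference of endogenous substances is judged on a volumetric mixing series:
each mix's RLU is compared against the dilution-expected value
``reference_rlu * parts_sample/total`` (the red-cell signal scales with the
blood fraction), and a series is flagged only if some mix deviates by strictly
more than the threshold — a deviation of exactly the threshold is acceptable.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats
from sklearn.base import BaseEstimator, RegressorMixin

from .errors import DegenerateDesignError, DomainError, InvalidCurveError

__all__ = [
    "HctStandardCurve",
    "HctEstimate",
    "InterferenceReport",
    "fit_standard_curve",
    "rlu_to_hct",
    "evaluate_interference",
]

#: Allowed extrapolation margin (HCT points) beyond the calibration range.
EXTRAPOLATION_MARGIN = 5.0


@dataclass(frozen=True)
class HctEstimate:
    """An inverted HCT estimate with quality flags."""

    value: float
    extrapolated: bool = False
    clamped: bool = False


class HctStandardCurve(RegressorMixin, BaseEstimator):
    """Linear RLU-vs-HCT standard curve, scikit-learn estimator style.

    ``fit(hct, rlu)`` runs OLS of RLU on HCT; ``predict(hct)`` evaluates the
    line; :meth:`estimate_hct` inverts a reading to an HCT estimate.

    Attributes
    ----------
    slope_ : float
        RLU per HCT percentage point.
    intercept_ : float
        Blank RLU at HCT 0.
    pearson_r_ : float
        Pearson correlation of the calibration points.
    range_low_, range_high_ : float
        HCT span of the calibration input.
    n_points_ : int
        Number of calibration pairs.
    """

    def fit(self, X, y=None):
        h = np.asarray(X, dtype=float).reshape(-1)
        rlu = np.asarray(y, dtype=float).reshape(-1)
        if h.size != rlu.size:
            raise DegenerateDesignError("hct and rlu lengths differ")
        if h.size < 3:
            raise DegenerateDesignError("need at least 3 calibration pairs")
        if np.unique(h).size < 2:
            raise DegenerateDesignError("all HCT values identical")
        res = stats.linregress(h, rlu)
        self.slope_ = float(res.slope)
        self.intercept_ = float(res.intercept)
        self.pearson_r_ = float(res.rvalue)
        self.range_low_ = float(np.min(h))
        self.range_high_ = float(np.max(h))
        self.n_points_ = int(h.size)
        return self

    @property
    def is_valid_(self) -> bool:
        """A curve is usable for inversion only with a positive slope."""
        return hasattr(self, "slope_") and self.slope_ > 0

    def predict(self, X):
        h = np.asarray(X, dtype=float).reshape(-1)
        return self.slope_ * h + self.intercept_

    def estimate_hct(self, rlu: float) -> HctEstimate:
        """Invert one RLU reading to an HCT estimate (%) with flags."""
        if not self.is_valid_:
            raise InvalidCurveError("standard curve has non-positive slope")
        value = (float(rlu) - self.intercept_) / self.slope_
        clamped = False
        if value < 0:
            value, clamped = 0.0, True
        extrapolated = not (
            self.range_low_ - EXTRAPOLATION_MARGIN
            <= value
            <= self.range_high_ + EXTRAPOLATION_MARGIN
        )
        return HctEstimate(value=value, extrapolated=extrapolated, clamped=clamped)

    def to_dict(self) -> dict:
        return {
            "slope": self.slope_,
            "intercept": self.intercept_,
            "pearson_r": self.pearson_r_,
            "range_low": self.range_low_,
            "range_high": self.range_high_,
            "n_points": self.n_points_,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "HctStandardCurve":
        curve = cls()
        curve.slope_ = float(d["slope"])
        curve.intercept_ = float(d["intercept"])
        curve.pearson_r_ = float(d["pearson_r"])
        curve.range_low_ = float(d["range_low"])
        curve.range_high_ = float(d["range_high"])
        curve.n_points_ = int(d["n_points"])
        return curve

    def to_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "HctStandardCurve":
        with open(path, encoding="utf-8") as fh:
            return cls.from_dict(json.load(fh))


def fit_standard_curve(pairs: Sequence[tuple[float, float]]) -> HctStandardCurve:
    """OLS standard curve from (HCT %, RLU) pairs."""
    arr = np.asarray(pairs, dtype=float)
    return HctStandardCurve().fit(arr[:, 0], arr[:, 1])


def rlu_to_hct(curve: HctStandardCurve, rlu: float) -> HctEstimate:
    """Invert an RLU reading on a fitted standard curve."""
    return curve.estimate_hct(rlu)


@dataclass(frozen=True)
class InterferenceReport:
    """Outcome of one interferent's mixing-series evaluation."""

    interferent: str
    max_abs_deviation: float
    flagged: bool
    per_ratio_deviation: tuple
    threshold: float = 10.0


def evaluate_interference(
    series_rlu: Sequence[tuple[tuple[float, float], float]],
    reference_rlu: float,
    threshold: float = 10.0,
    interferent: str = "",
) -> InterferenceReport:
    """Judge an interferent by RLU deviation from the dilution expectation.

    ``series_rlu`` holds ``((parts_sample, parts_stock), mean RLU)`` entries.
    The expected RLU of a mix is ``reference_rlu * parts_sample / total``;
    per-ratio deviation is ``100 * (observed - expected) / expected``. Ratios
    with no blood fraction (expected 0) carry no information and are skipped.
    The series is flagged iff some |deviation| strictly exceeds ``threshold``.
    """
    if reference_rlu <= 0:
        raise DomainError("reference_rlu must be > 0")
    if not series_rlu:
        raise DomainError("series must be nonempty")
    deviations = []
    for (ps, pk), observed in series_rlu:
        total = ps + pk
        if total <= 0 or ps < 0 or pk < 0:
            raise DomainError(f"invalid ratio ({ps}, {pk})")
        expected = reference_rlu * ps / total
        if expected == 0:
            continue
        deviations.append(100.0 * (observed - expected) / expected)
    max_abs = float(max(abs(d) for d in deviations)) if deviations else 0.0
    return InterferenceReport(
        interferent=interferent,
        max_abs_deviation=max_abs,
        flagged=max_abs > threshold,
        per_ratio_deviation=tuple(float(d) for d in deviations),
        threshold=float(threshold),
    )
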