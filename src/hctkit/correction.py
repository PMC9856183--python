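"""Two-stage hematocrit correction of whole-blood immunoassay concentrations.

A concentration measured by immunoassay directly in whole blood under-reads the
plasma concentration for two reasons:

1. **Plasma-volume displacement.** Only the plasma fraction ``1 - HCT/100`` of
   the aspirated volume carries the analyte, so the whole-blood reading scales
   down by that factor. Inverting it is the classical plasma-equivalent
   conversion::

       C_plasma = C_wb / (1 - HCT/100)

2. **Residual assay bias.** Red cells and cell debris also slow immune binding,
   leaving a residual percent under-recovery *after* the volume conversion.
   That residual grows sigmoidally with HCT and is modelled by a
   four-parameter logistic (4PL) curve

       y(h) = upper - (upper - lower) / (1 + (h / inflection)^hill)

   where ``y`` is the residual relative difference in percent and ``h`` the
   hematocrit in percent. The second correction stage divides by
   ``1 - y(h)/100``.

Both stages are multiplicative, hence commute; applied together they exactly
invert the suppression model used by :mod:`hctkit.simulate`.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Sequence

import numpy as np
from scipy import optimize, stats
from sklearn.base import BaseEstimator, RegressorMixin, TransformerMixin

from .errors import (
    ConvergenceError,
    DegenerateDesignError,
    DomainError,
    ModelDomainError,
)

__all__ = [
    "FourPLParams",
    "REFERENCE_CTNI_BIAS",
    "CorrectionResult",
    "RecoverySummary",
    "FourPLBiasModel",
    "HctCorrector",
    "plasma_equivalent",
    "fourpl_eval",
    "fit_fourpl",
    "correct_two_stage",
    "recovery",
    "HCT_VALID_RANGE",
]

#: HCT window (%) over which the correction is considered validated; results
#: outside it are returned flagged, never refused.
HCT_VALID_RANGE = (0.0, 65.0)


@dataclass(frozen=True)
class FourPLParams:
    """Parameters of the 4PL residual-bias curve.

    Attributes
    ----------
    lower : float
        Asymptote of the residual deviation (%) as HCT -> 0.
    upper : float
        Asymptote (%) as HCT -> infinity. Must stay below 100 so the
        correction divisor ``1 - y/100`` remains positive.
    inflection : float
        HCT (%) at the curve midpoint; must be positive.
    hill : float
        Steepness (dimensionless); must be positive for an increasing curve.
    """

    lower: float
    upper: float
    inflection: float
    hill: float

    def __post_init__(self) -> None:
        if not self.hill > 0:
            raise DomainError(f"hill must be > 0, got {self.hill}")
        if not self.inflection > 0:
            raise DomainError(f"inflection must be > 0, got {self.inflection}")
        if not self.lower < self.upper:
            raise DomainError(
                f"lower ({self.lower}) must be < upper ({self.upper})"
            )
        if not self.upper < 100:
            raise DomainError(f"upper must be < 100, got {self.upper}")

    @property
    def span(self) -> float:
        """upper - lower, the dynamic range of the bias curve (%)."""
        return self.upper - self.lower

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "FourPLParams":
        return cls(
            lower=float(d["lower"]),
            upper=float(d["upper"]),
            inflection=float(d["inflection"]),
            hill=float(d["hill"]),
        )


#: Reference residual-bias curve for the cTnI assay (upper asymptote 34.145%,
#: span 31.816%, inflection 52.155% HCT, hill 9.175). Shipped as the default
#: bias model for cTnI scenarios; other assays need their own fit.
REFERENCE_CTNI_BIAS = FourPLParams(
    lower=34.145 - 31.816, upper=34.145, inflection=52.155, hill=9.175
)


def fourpl_eval(params: FourPLParams, hct):
    """Evaluate the residual-bias curve y(h) in percent.

    Accepts a scalar or array HCT in [0, inf); strictly increasing in ``hct``
    for a positive hill slope. Raises :class:`DomainError` for negative HCT.
    """
    h = np.asarray(hct, dtype=float)
    if np.any(h < 0):
        raise DomainError("HCT must be >= 0")
    with np.errstate(divide="ignore"):
        ratio = np.where(h > 0, h / params.inflection, 0.0)
        y = params.upper - params.span / (1.0 + np.power(ratio, params.hill))
    return float(y) if np.isscalar(hct) or y.ndim == 0 else y


def plasma_equivalent(conc_wb, hct):
    """Convert a whole-blood concentration to its plasma-equivalent value.

    ``C_plasma = C_wb / (1 - HCT/100)``. Diverges as HCT -> 100;
    :class:`DomainError` is raised at or above 100 and below 0.
    """
    c = np.asarray(conc_wb, dtype=float)
    h = np.asarray(hct, dtype=float)
    if np.any(c < 0):
        raise DomainError("concentration must be >= 0")
    if np.any((h < 0) | (h >= 100)):
        raise DomainError("HCT must lie in [0, 100)")
    out = c / (1.0 - h / 100.0)
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class CorrectionResult:
    """One measurement traced through the correction chain.

    ``raw_wb`` -> ``volume_corrected`` (plasma-equivalent) -> ``final_value``
    (bias-compensated), with the HCT actually used and the residual deviation
    (%) applied at stage two. ``flagged`` marks an HCT outside the validated
    window rather than an error.
    """

    raw_wb: float
    hct_used: float
    volume_corrected: float
    final_value: float
    deviation_applied: float
    flagged: bool = False


def correct_two_stage(
    conc_wb: float, hct: float, params: FourPLParams
) -> CorrectionResult:
    """Apply the plasma-volume and residual-bias corrections in sequence.

    Raises :class:`DomainError` for HCT outside [0, 100) and
    :class:`ModelDomainError` if the bias curve reaches 100% (divisor <= 0).
    HCT outside the validated window only flags the result.
    """
    vol = plasma_equivalent(conc_wb, hct)
    y = fourpl_eval(params, hct)
    if y >= 100:
        raise ModelDomainError(
            f"bias model evaluates to {y:.3f}% >= 100% at HCT {hct}"
        )
    final = vol / (1.0 - y / 100.0)
    flagged = not (HCT_VALID_RANGE[0] <= hct <= HCT_VALID_RANGE[1])
    return CorrectionResult(
        raw_wb=float(conc_wb),
        hct_used=float(hct),
        volume_corrected=float(vol),
        final_value=float(final),
        deviation_applied=float(y),
        flagged=flagged,
    )


class FourPLBiasModel(RegressorMixin, BaseEstimator):
    """Four-parameter logistic model of residual assay bias vs hematocrit.

    scikit-learn style estimator: ``fit(hct, deviation)`` estimates the four
    parameters by bounded nonlinear least squares; ``predict(hct)`` evaluates
    the fitted curve. Parameters may instead be supplied directly at
    construction for a pre-calibrated assay.

    Parameters
    ----------
    params : FourPLParams, optional
        Known parameters; if given, ``predict`` works without fitting.
    maxfev : int
        Function-evaluation budget for the least-squares solver.

    Attributes
    ----------
    params_ : FourPLParams
        Fitted (or supplied) parameters.
    lower_, upper_, inflection_, hill_ : float
        The individual fitted parameters.
    pearson_r_ : float
        Pearson correlation between fitted and observed deviations.
    """

    def __init__(self, params: FourPLParams | None = None, maxfev: int = 20000):
        self.params = params
        self.maxfev = maxfev

    # -- initialisation heuristics ------------------------------------------
    @staticmethod
    def _auto_init(h: np.ndarray, y: np.ndarray) -> tuple[float, float, float, float]:
        ymin, ymax = float(np.min(y)), float(np.max(y))
        span = ymax - ymin
        if span <= 0:
            raise DegenerateDesignError("flat deviations: 4PL is unidentifiable")
        a0 = ymin - 0.05 * span
        d0 = ymax + 0.05 * span
        # inflection: HCT at the midpoint crossing, linearly interpolated
        mid = 0.5 * (a0 + d0)
        order = np.argsort(h)
        hs, ys = h[order], y[order]
        c0 = float(np.median(hs[hs > 0])) if np.any(hs > 0) else 40.0
        above = np.nonzero(ys >= mid)[0]
        if above.size and above[0] > 0:
            i = above[0]
            f = (mid - ys[i - 1]) / (ys[i] - ys[i - 1])
            c0 = float(hs[i - 1] + f * (hs[i] - hs[i - 1]))
        c0 = min(max(c0, 1.0), 99.0)
        # hill: log-linearised slope of ln((y-a)/(d-y)) on ln(h)
        mask = (h > 0) & (y > a0) & (y < d0)
        b0 = 5.0
        if np.count_nonzero(mask) >= 2:
            lx = np.log(h[mask])
            lz = np.log((y[mask] - a0) / (d0 - y[mask]))
            if np.ptp(lx) > 0:
                b0 = float(np.polyfit(lx, lz, 1)[0])
        b0 = min(max(b0, 0.5), 30.0)
        return a0, d0, c0, b0

    def fit(self, X, y=None):
        """Fit the 4PL curve to (HCT %, deviation %) points.

        ``X`` is a 1-D array of HCT values (or an (n, 1) column), ``y`` the
        observed percent deviations. Requires >= 5 points with >= 4 distinct
        HCT values.
        """
        if self.params is not None and X is None:
            self.params_ = self.params
            self._unpack()
            return self
        h = np.asarray(X, dtype=float).reshape(-1)
        dev = np.asarray(y, dtype=float).reshape(-1)
        if h.size != dev.size:
            raise DegenerateDesignError("hct and deviation lengths differ")
        if h.size < 5:
            raise DegenerateDesignError("need at least 5 points to fit a 4PL")
        if np.unique(h).size < 4:
            raise DegenerateDesignError("need at least 4 distinct HCT values")
        if np.any(h < 0):
            raise DomainError("HCT must be >= 0")

        p0 = self.params
        if p0 is not None:
            init = (p0.lower, p0.upper, p0.inflection, p0.hill)
        else:
            init = self._auto_init(h, dev)

        def model(x, a, d, c, b):
            ratio = np.where(x > 0, x / c, 0.0)
            return d - (d - a) / (1.0 + np.power(ratio, b))

        bounds = ([-100.0, -100.0, 1e-6, 1e-6], [100.0, 100.0, 100.0, 50.0])
        init = np.clip(init, bounds[0], bounds[1])
        try:
            popt, _ = optimize.curve_fit(
                model, h, dev, p0=init, bounds=bounds, maxfev=self.maxfev
            )
        except RuntimeError as exc:  # solver exhausted its budget
            raise ConvergenceError(str(exc), best_params=tuple(init)) from exc
        a, d, c, b = (float(v) for v in popt)
        if not a < d:
            raise DegenerateDesignError(
                "degenerate fit: lower asymptote >= upper asymptote"
            )
        self.params_ = FourPLParams(lower=a, upper=d, inflection=c, hill=b)
        self._unpack()
        fitted = model(h, a, d, c, b)
        if np.std(fitted) > 0 and np.std(dev) > 0:
            self.pearson_r_ = float(stats.pearsonr(fitted, dev)[0])
        else:
            self.pearson_r_ = float("nan")
        self.n_points_ = int(h.size)
        return self

    def _unpack(self) -> None:
        p = self.params_
        self.lower_, self.upper_ = p.lower, p.upper
        self.inflection_, self.hill_ = p.inflection, p.hill

    def predict(self, X):
        """Evaluate the fitted bias curve at the given HCT values (%)."""
        if not hasattr(self, "params_"):
            if self.params is None:
                raise DegenerateDesignError("model is neither fitted nor preset")
            self.params_ = self.params
            self._unpack()
        h = np.asarray(X, dtype=float).reshape(-1)
        return fourpl_eval(self.params_, h)


def fit_fourpl(
    points: Sequence[tuple[float, float]],
    init: FourPLParams | None = None,
    maxfev: int = 20000,
) -> tuple[FourPLParams, float]:
    """Fit the 4PL bias curve to (HCT, deviation) pairs.

    Thin wrapper over :class:`FourPLBiasModel`; returns the fitted parameters
    and the Pearson r between fitted and observed deviations.
    """
    pts = np.asarray(points, dtype=float)
    model = FourPLBiasModel(params=init, maxfev=maxfev)
    model.fit(pts[:, 0], pts[:, 1])
    return model.params_, model.pearson_r_


class HctCorrector(TransformerMixin, BaseEstimator):
    """Transformer applying the HCT correction to (concentration, HCT) rows.

    ``transform`` takes an (n, 2) array whose columns are the raw whole-blood
    concentration and the HCT (%) used for correction, and returns the
    corrected concentrations. ``mode='volume_only'`` stops after the
    plasma-equivalent stage; ``mode='two_stage'`` (default) also divides out
    the residual bias.
    """

    def __init__(
        self,
        params: FourPLParams | None = None,
        mode: str = "two_stage",
    ):
        self.params = params
        self.mode = mode

    def fit(self, X=None, y=None):
        if self.mode not in ("two_stage", "volume_only"):
            raise DomainError(f"unknown mode {self.mode!r}")
        if self.mode == "two_stage" and self.params is None:
            raise DomainError("two_stage mode requires bias-model params")
        self.params_ = self.params
        return self

    def transform(self, X):
        if not hasattr(self, "params_"):
            self.fit()
        arr = np.asarray(X, dtype=float)
        if arr.ndim != 2 or arr.shape[1] != 2:
            raise DomainError("expected an (n, 2) array of (conc, hct)")
        conc, hct = arr[:, 0], arr[:, 1]
        out = plasma_equivalent(conc, hct)
        if self.mode == "two_stage":
            y = fourpl_eval(self.params_, hct)
            if np.any(y >= 100):
                raise ModelDomainError("bias model reaches 100% in input range")
            out = out / (1.0 - y / 100.0)
        return np.asarray(out, dtype=float)


@dataclass(frozen=True)
class RecoverySummary:
    """Per-sample recoveries (%) and their summary statistics."""

    per_sample: tuple
    mean: float
    min: float
    max: float
    n: int


def recovery(measured, truth) -> RecoverySummary:
    """Percent recovery of measured vs true concentrations.

    ``100 * measured / truth`` per sample, summarised by mean/min/max.
    Raises for length mismatch or non-positive truths.
    """
    m = np.asarray(measured, dtype=float)
    t = np.asarray(truth, dtype=float)
    if m.shape != t.shape or m.size < 1:
        raise DomainError("measured and truth must be equal-length, nonempty")
    if np.any(t <= 0):
        raise DomainError("true concentrations must be > 0")
    rec = 100.0 * m / t
    return RecoverySummary(
        per_sample=tuple(float(r) for r in rec),
        mean=float(np.mean(rec)),
        min=float(np.min(rec)),
        max=float(np.max(rec)),
        n=int(rec.size),
    )
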