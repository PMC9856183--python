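"""Method-comparison and precision statistics for clinical assays.

Implements the evaluation toolbox used to validate a new measurement method
against an established one:

- **Passing–Bablok regression** — nonparametric structural regression whose
  slope is the shifted median of all pairwise slopes. Robust to outliers,
  scale-invariant, and symmetric in the two methods up to slope inversion.
  Implemented from first principles (it is the statistic under test, not a
  convenience call).
- **Bland–Altman agreement** — mean bias, SD of differences, 1.96-SD limits
  of agreement and a t-based confidence interval for the mean bias, in
  absolute units or as percent of the pairwise mean.
- **Pearson correlation / R².**
- **Repeatability CV** with chi-square confidence limits on the SD propagated
  to the CV (the CLSI-style first-order interval).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps
from sklearn.base import BaseEstimator, RegressorMixin

from .errors import DegenerateDesignError, DomainError

__all__ = [
    "PassingBablok",
    "PBResult",
    "BAResult",
    "PrecisionResult",
    "passing_bablok",
    "bland_altman",
    "correlation",
    "repeatability_cv",
]


@dataclass(frozen=True)
class PBResult:
    """Passing–Bablok slope/intercept with 95% confidence intervals."""

    slope: float
    intercept: float
    slope_ci: tuple
    intercept_ci: tuple
    n: int
    n_slopes: int


class PassingBablok(RegressorMixin, BaseEstimator):
    """Passing–Bablok method-comparison regression (scikit-learn style).

    Slope estimate: sort the ``N`` valid pairwise slopes
    ``S_ij = (y_j - y_i)/(x_j - x_i)``; with ``K`` the count of slopes below
    -1, the estimate is the order statistic at position ``(N+1)/2 + K``
    (1-indexed; the arithmetic mean of the two middle shifted positions for
    even ``N``). Slopes equal to -1 are excluded; tied ``x`` with differing
    ``y`` contributes a signed infinite slope, which sorting places at the
    ordering extremes; fully tied pairs carry no information. The intercept
    is ``median(y - slope*x)``. Confidence intervals use the rank-based
    normal approximation; intercept bounds reuse the slope bounds.

    Attributes: ``slope_``, ``intercept_``, ``slope_ci_``, ``intercept_ci_``,
    ``n_``, ``n_slopes_``.
    """

    def __init__(self, alpha: float = 0.05):
        self.alpha = alpha

    def fit(self, X, y=None):
        x = np.asarray(X, dtype=float).reshape(-1)
        yv = np.asarray(y, dtype=float).reshape(-1)
        if x.size != yv.size:
            raise DegenerateDesignError("x and y lengths differ")
        n = x.size
        if n < 3:
            raise DegenerateDesignError("need at least 3 pairs")
        if np.unique(x).size < 2:
            raise DegenerateDesignError("all x values identical")

        slopes: list[float] = []
        for i in range(n - 1):
            dx = x[i + 1:] - x[i]
            dy = yv[i + 1:] - yv[i]
            for dxi, dyi in zip(dx, dy):
                if dxi == 0:
                    if dyi == 0:
                        continue  # identical points: no information
                    slopes.append(np.inf if dyi > 0 else -np.inf)
                else:
                    s = dyi / dxi
                    if s == -1.0:
                        continue
                    slopes.append(s)
        N = len(slopes)
        if N == 0:
            raise DegenerateDesignError("no valid pairwise slopes")
        S = np.sort(np.asarray(slopes, dtype=float))
        K = int(np.sum(S < -1.0))

        def shifted(pos: int) -> float:
            # 1-indexed order statistic with offset K, clipped into range
            return float(S[min(max(pos + K, 1), N) - 1])

        if N % 2 == 1:
            b = shifted((N + 1) // 2)
        else:
            b = 0.5 * (shifted(N // 2) + shifted(N // 2 + 1))

        w = sps.norm.ppf(1.0 - self.alpha / 2.0)
        C = w * np.sqrt(n * (n - 1) * (2 * n + 5) / 18.0)
        m1 = int(round((N - C) / 2.0))
        m2 = N - m1 + 1
        b_lo, b_hi = shifted(m1), shifted(m2)

        a = float(np.median(yv - b * x))
        with np.errstate(invalid="ignore"):
            a_lo = float(np.median(yv - b_hi * x))
            a_hi = float(np.median(yv - b_lo * x))

        self.slope_ = float(b)
        self.intercept_ = a
        self.slope_ci_ = (b_lo, b_hi)
        self.intercept_ci_ = (a_lo, a_hi)
        self.n_ = int(n)
        self.n_slopes_ = int(N)
        return self

    def predict(self, X):
        x = np.asarray(X, dtype=float).reshape(-1)
        return self.slope_ * x + self.intercept_

    def result_(self) -> PBResult:
        return PBResult(
            slope=self.slope_,
            intercept=self.intercept_,
            slope_ci=self.slope_ci_,
            intercept_ci=self.intercept_ci_,
            n=self.n_,
            n_slopes=self.n_slopes_,
        )


def passing_bablok(x, y, alpha: float = 0.05) -> PBResult:
    """Passing–Bablok regression of method y on method x."""
    return PassingBablok(alpha=alpha).fit(x, y).result_()


@dataclass(frozen=True)
class BAResult:
    """Bland–Altman agreement summary.

    ``mode`` is ``'absolute'`` (differences in measurement units) or
    ``'relative'`` (percent of the pairwise mean). ``loa`` is the 1.96-SD
    limits-of-agreement pair, ``ci_mean`` the t-based CI of the mean bias.
    """

    mode: str
    mean_bias: float
    sd_bias: float
    loa: tuple
    ci_mean: tuple
    n: int


def bland_altman(x, y, mode: str = "absolute", alpha: float = 0.05) -> BAResult:
    """Bland–Altman differences of method y minus method x."""
    xv = np.asarray(x, dtype=float).reshape(-1)
    yv = np.asarray(y, dtype=float).reshape(-1)
    if xv.size != yv.size or xv.size < 2:
        raise DomainError("need equal-length arrays with n >= 2")
    if mode == "absolute":
        d = yv - xv
    elif mode == "relative":
        means = 0.5 * (xv + yv)
        if np.any(means <= 0):
            raise DomainError("relative mode requires positive pairwise means")
        d = 100.0 * (yv - xv) / means
    else:
        raise DomainError(f"unknown mode {mode!r}")
    n = d.size
    mean = float(np.mean(d))
    sd = float(np.std(d, ddof=1))
    half = sps.t.ppf(1.0 - alpha / 2.0, n - 1) * sd / np.sqrt(n)
    return BAResult(
        mode=mode,
        mean_bias=mean,
        sd_bias=sd,
        loa=(mean - 1.96 * sd, mean + 1.96 * sd),
        ci_mean=(mean - float(half), mean + float(half)),
        n=int(n),
    )


def correlation(x, y) -> tuple[float, float]:
    """Pearson correlation coefficient and its square."""
    xv = np.asarray(x, dtype=float).reshape(-1)
    yv = np.asarray(y, dtype=float).reshape(-1)
    if xv.size != yv.size or xv.size < 3:
        raise DegenerateDesignError("need equal-length arrays with n >= 3")
    if np.std(xv) == 0 or np.std(yv) == 0:
        raise DegenerateDesignError("zero variance in an input")
    r = float(sps.pearsonr(xv, yv)[0])
    return r, r * r


@dataclass(frozen=True)
class PrecisionResult:
    """Repeatability summary: mean, SD, CV% and its confidence limits."""

    mean: float
    sd: float
    cv: float
    cv_ci: tuple
    n: int


def repeatability_cv(replicates, alpha: float = 0.05) -> PrecisionResult:
    """CV% of replicate measurements with chi-square confidence limits.

    ``cv = 100*sd/mean``; the interval scales cv by
    ``sqrt((n-1)/chi2_q)`` at the upper/lower chi-square quantiles of the
    variance (first-order propagation from SD to CV).
    """
    r = np.asarray(replicates, dtype=float).reshape(-1)
    n = r.size
    if n < 2:
        raise DomainError("need at least 2 replicates")
    mean = float(np.mean(r))
    if mean <= 0:
        raise DomainError("replicate mean must be > 0")
    sd = float(np.std(r, ddof=1))
    cv = 100.0 * sd / mean
    if sd == 0:
        ci = (0.0, 0.0)
    else:
        lo = cv * np.sqrt((n - 1) / sps.chi2.ppf(1.0 - alpha / 2.0, n - 1))
        hi = cv * np.sqrt((n - 1) / sps.chi2.ppf(alpha / 2.0, n - 1))
        ci = (float(lo), float(hi))
    return PrecisionResult(mean=mean, sd=sd, cv=float(cv), cv_ci=ci, n=int(n))
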