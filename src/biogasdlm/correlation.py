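"""Cross-correlation screening between feeding and biogas production.

Before committing to lagged feeding as a predictor, the sample
cross-correlation function (CCF) between the feeding series x and the
production series y is inspected: lags where |r| exceeds the white-noise
bound z₀.₉₇₅/√n indicate that past feeding carries information about current
production and justify a distributed-lag model.

Sign convention: a *positive* lag h means x leads y, i.e. r(h) correlates
x(t−h) with y(t) — the direction the lag model uses.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .exceptions import BoundsError, DegenerateInputError

__all__ = ["CCFResult", "SignificantLag", "cross_correlate", "significant_lags"]


@dataclass(frozen=True)
class CCFResult:
    """Sample CCF over lags −max_lag…+max_lag with a white-noise bound."""

    lags: np.ndarray            # integer offsets
    correlations: np.ndarray    # in [-1, 1], same length as lags
    n: int                      # number of paired observations
    conf_bound: float           # z_0.975 / sqrt(n)


@dataclass(frozen=True)
class SignificantLag:
    lag: int
    correlation: float
    sign: str  # "positive" | "negative"


def cross_correlate(x: np.ndarray, y: np.ndarray, max_lag: int) -> CCFResult:
    """Sample cross-correlation of x and y at lags −max_lag…+max_lag.

    Uses the conventional estimator with the denominator fixed at the
    full-sample (biased, 1/n) standard deviations:

        r(h) = (1/n) Σ_t (x(t−h) − x̄)(y(t) − ȳ) / (s_x s_y)

    which is the estimator standard time-series CCF routines implement.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise BoundsError("x and y must be equal-length 1-d series")
    n = x.size
    if max_lag < 0 or max_lag >= n:
        raise BoundsError(f"need 0 <= max_lag < n, got max_lag={max_lag}, n={n}")
    if n <= max_lag + 2:
        raise BoundsError(f"series length {n} too short for max_lag={max_lag}")

    xc = x - x.mean()
    yc = y - y.mean()
    sx = np.sqrt(np.mean(xc**2))
    sy = np.sqrt(np.mean(yc**2))
    if sx == 0 or sy == 0:
        which = "x" if sx == 0 else "y"
        raise DegenerateInputError(f"series {which} has zero variance")

    # full cross-covariance via correlate: cc[k] = Σ_t xc[t] yc[t + (k − (n−1))]
    cc = np.correlate(yc, xc, mode="full")  # index n-1 ↔ lag 0, n-1+h ↔ x leads by h
    lags = np.arange(-max_lag, max_lag + 1)
    corr = cc[(n - 1) + lags] / (n * sx * sy)

    z = stats.norm.ppf(0.975)
    return CCFResult(lags=lags, correlations=corr, n=n, conf_bound=float(z / np.sqrt(n)))


def significant_lags(result: CCFResult) -> list[SignificantLag]:
    """Lags whose |correlation| exceeds the white-noise bound, with sign."""
    out = []
    for lag, r in zip(result.lags, result.correlations):
        if abs(r) > result.conf_bound:
            out.append(
                SignificantLag(
                    lag=int(lag),
                    correlation=float(r),
                    sign="positive" if r > 0 else "negative",
                )
            )
    return out
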