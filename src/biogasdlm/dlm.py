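"""Distributed-lag regression of biogas production on substrate feeding.

The model is

    Y(t) = α + Σ_r Σ_{j=0}^{k} β_{r,j} · X_r(t−j) + ε(t)

where Y is hourly biogas production (m³ h⁻¹), X_r are the feeding regressors
(kg h⁻¹; solid substrate, optionally liquid manure), k is the lag order and
α the intercept (m³ h⁻¹).  The coefficients β (m³ kg⁻¹) distribute the
specific gas yield of one kilogram of substrate over the k+1 hours after
feeding, which is what makes them directly interpretable as gas-formation
kinetics (see :mod:`biogasdlm.kinetics`).

Fitting is ordinary least squares on a lagged design matrix.  Because the
right-hand side contains only feeding (no autoregressive Y terms),
multi-step simulation over a horizon H needs no recursion: given a planned
feeding schedule and the last k observed feeding values, ŷ is a direct
evaluation of the model at every future hour.

Coefficients are never regularised or standardised — they must stay in
m³ kg⁻¹ — and a rank-deficient design (e.g. a window with no feeding at
all, or perfectly periodic dosing) is a hard error, never silently repaired.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence, Union

import numpy as np
import scipy.linalg

from .exceptions import BoundsError, SchemaError, SingularDesignError
from .timeseries import Instant, PlantSeries

__all__ = ["ModelConfig", "LaggedDesign", "FittedDLM", "build_design", "fit_ols", "simulate"]

#: relative tolerance for the rank check in :func:`fit_ols`
RANK_RTOL = 1e-10

FeedInput = Union[np.ndarray, Sequence[float], Mapping[str, Union[np.ndarray, Sequence[float]]]]


@dataclass(frozen=True)
class ModelConfig:
    """Model settings: lag order k, training length T, horizon H, regressors.

    The settings the evaluation grid explores are k ∈ {48, 72, 96} lags,
    T ∈ {200, 500, 800} hourly observations and H ∈ {48, 96, 144} hours.
    """

    lag_order: int = 48
    training_length: int = 500
    horizon: int = 48
    regressors: tuple = ("solid_feed",)
    clamp_nonnegative: bool = True

    def __post_init__(self):
        object.__setattr__(self, "regressors", tuple(self.regressors))
        if self.lag_order < 0:
            raise BoundsError(f"lag_order must be >= 0, got {self.lag_order}")
        if self.horizon < 1:
            raise BoundsError(f"horizon must be >= 1, got {self.horizon}")
        if not self.regressors:
            raise SchemaError("at least one regressor is required")
        if self.training_length <= self.n_params:
            raise BoundsError(
                f"training_length {self.training_length} must exceed the "
                f"{self.n_params} fitted parameters"
            )

    @property
    def n_params(self) -> int:
        return 1 + len(self.regressors) * (self.lag_order + 1)


@dataclass(frozen=True)
class LaggedDesign:
    """OLS-ready design: intercept column, then lag-0…k columns per regressor.

    Every lagged value is an actually observed history value — rows near the
    window start draw on the warm-up rows, never on implicit zero padding.
    """

    response: np.ndarray        # (T,)
    matrix: np.ndarray          # (T, 1 + Σ_r (k+1))
    columns: tuple              # column names, "intercept", "<reg>_lag<j>"
    config: ModelConfig
    train_end: object           # timestamp label of the last training row


def build_design(series: PlantSeries, config: ModelConfig, train_end: Instant) -> LaggedDesign:
    """Lagged design matrix for the T training rows ending at ``train_end``."""
    k, T = config.lag_order, config.training_length
    for reg in config.regressors:
        if reg not in series.regressors:
            raise SchemaError(f"regressor {reg!r} absent from series {series.digester_id}")

    end = series.index_of(train_end)
    start = end - T + 1  # first training row
    if start - k < 0:
        raise BoundsError(
            f"training window of {T} rows ending at position {end} needs {k} "
            f"warm-up rows before it; only {start} available"
        )

    cols = [np.ones(T)]
    names = ["intercept"]
    for reg in config.regressors:
        x = series.regressor(reg)
        for j in range(k + 1):
            cols.append(x[start - j : end - j + 1])
            names.append(f"{reg}_lag{j}")

    return LaggedDesign(
        response=series.biogas[start : end + 1].copy(),
        matrix=np.column_stack(cols),
        columns=tuple(names),
        config=config,
        train_end=series.timestamps[end],
    )


@dataclass(frozen=True)
class FittedDLM:
    """An OLS-fitted distributed-lag model.

    ``betas[r][j]`` is the expected extra biogas (m³) produced in hour t per
    kg of regressor r fed at hour t−j.  Residuals are in m³ h⁻¹ and average
    zero (the design has an intercept).
    """

    intercept: float                    # α, m³ h⁻¹
    betas: Mapping[str, np.ndarray]     # per regressor, β0…βk in m³ kg⁻¹
    residuals: np.ndarray               # (T,)
    config: ModelConfig
    train_end: object

    @property
    def lag_order(self) -> int:
        return self.config.lag_order


def fit_ols(design: LaggedDesign) -> FittedDLM:
    """Fit by QR least squares with a hard rank check.

    Uses column-pivoted QR; a design whose trailing pivoted diagonal falls
    below RANK_RTOL·‖X‖ is reported as singular, naming the offending
    columns.  Degenerate windows (zero feeding throughout, exactly periodic
    dosing) must surface loudly rather than yield garbage kinetics.
    """
    X, y = design.matrix, design.response
    n, p = X.shape
    if n <= p:
        raise BoundsError(f"need more rows than columns, got {n} x {p}")

    Q, R, perm = scipy.linalg.qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(R))
    tol = RANK_RTOL * np.linalg.norm(X)
    rank = int(np.sum(diag > tol))
    if rank < p:
        offending = tuple(design.columns[j] for j in sorted(perm[rank:]))
        raise SingularDesignError(
            f"design matrix is rank deficient (rank {rank} < {p}); "
            f"offending column(s): {', '.join(offending)}",
            columns=offending,
        )

    coef_p = scipy.linalg.solve_triangular(R, Q.T @ y)
    coef = np.empty(p)
    coef[perm] = coef_p
    residuals = y - X @ coef

    k = design.config.lag_order
    betas = {}
    pos = 1
    for reg in design.config.regressors:
        betas[reg] = coef[pos : pos + k + 1].copy()
        pos += k + 1

    return FittedDLM(
        intercept=float(coef[0]),
        betas=betas,
        residuals=residuals,
        config=design.config,
        train_end=design.train_end,
    )


def _as_feed_dict(value: FeedInput, regressors: tuple, what: str) -> dict:
    if isinstance(value, Mapping):
        d = {r: np.asarray(v, dtype=float) for r, v in value.items()}
    elif len(regressors) == 1:
        d = {regressors[0]: np.asarray(value, dtype=float)}
    else:
        raise SchemaError(f"{what} must be a mapping for a multi-regressor model")
    missing = set(regressors) - set(d)
    extra = set(d) - set(regressors)
    if missing or extra:
        raise SchemaError(
            f"{what} regressors {sorted(d)} do not match model regressors {list(regressors)}"
        )
    return d


def simulate(
    model: FittedDLM,
    planned_feed: FeedInput,
    recent_history: Optional[FeedInput] = None,
    clamp: Optional[bool] = None,
) -> np.ndarray:
    """Simulate biogas production over the planned feeding schedule.

    Parameters
    ----------
    planned_feed
        Future feeding values (kg h⁻¹), one array of equal length H per
        regressor (a bare array is accepted for single-regressor models).
    recent_history
        The last ≥k observed feeding values per regressor, supplying the
        lagged values for the first simulated hours.  May be omitted when
        k = 0.
    clamp
        Overrides ``model.config.clamp_nonnegative``.  When active, ŷ is
        floored at 0 element-wise after evaluation (biogas production is
        physically non-negative); leave off for coefficient/residual work.

    Returns the simulated production ŷ (m³ h⁻¹), length H.
    """
    k = model.lag_order
    regs = model.config.regressors
    planned = _as_feed_dict(planned_feed, regs, "planned_feed")
    H = len(next(iter(planned.values())))
    if H < 1 or any(len(v) != H for v in planned.values()):
        raise BoundsError("planned_feed arrays must share a common length H >= 1")

    if recent_history is None:
        history = {r: np.empty(0) for r in regs}
    else:
        history = _as_feed_dict(recent_history, regs, "recent_history")
    for r in regs:
        if len(history[r]) < k:
            raise BoundsError(
                f"recent_history for {r!r} has {len(history[r])} values; "
                f"need at least k = {k}"
            )

    yhat = np.full(H, model.intercept)
    for r in regs:
        full = np.concatenate([history[r][len(history[r]) - k :], planned[r]])
        # conv[m] = Σ_j full[m−j]·β_j ; hour t of the forecast sits at m = k+t
        conv = np.convolve(full, model.betas[r])
        yhat += conv[k : k + H]

    do_clamp = model.config.clamp_nonnegative if clamp is None else clamp
    if do_clamp:
        yhat = np.maximum(yhat, 0.0)
    return yhat
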