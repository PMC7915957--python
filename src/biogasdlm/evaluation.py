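"""Forecast accuracy metrics and rolling-origin evaluation.

Accuracy of a simulated trajectory zˢ against observations z is measured by

    MAPE = (1/E′) Σ |z − zˢ| / z · 100 %      (hours with z = 0 excluded)
    MAE  = (1/E)  Σ |z − zˢ|                  (m³ h⁻¹)
    RMSE = √((1/E) Σ (z − zˢ)²)               (m³ h⁻¹)

MAPE divides by the observation, and real plant data contain genuine
zero-production hours (downtime), so those hours are dropped from the MAPE
sum only — they stay in MAE/RMSE — and the exclusion count is reported.

The rolling-origin evaluation refits the model every ``step`` (default 24)
hours through the series — this rolling re-training is what makes the model
self-learning — and scores an H-hour simulation at each origin against the
recorded production, using the recorded feeding as the "planned" schedule
(hindcast).  The settings grid summarises mean per-run accuracy over the
T × k × H grid; by default the three horizons share fits, a horizon-144 run
containing its 48- and 96-hour prefixes, which makes the horizon comparison
paired and cheap.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .dlm import FittedDLM, ModelConfig, build_design, fit_ols, simulate
from .exceptions import (
    BoundsError,
    EvaluationError,
    SingularDesignError,
    UndefinedMetricError,
)
from .timeseries import PlantSeries

__all__ = [
    "MAPEResult",
    "SimulationRun",
    "EvaluationReport",
    "mape",
    "mae",
    "rmse",
    "count_origins",
    "rolling_evaluate",
    "grid_report",
]

logger = logging.getLogger(__name__)


def _check_pair(observed, simulated):
    z = np.asarray(observed, dtype=float)
    zs = np.asarray(simulated, dtype=float)
    if z.shape != zs.shape or z.ndim != 1 or z.size < 1:
        raise BoundsError(
            f"observed and simulated must be equal-length 1-d vectors, "
            f"got shapes {z.shape} and {zs.shape}"
        )
    return z, zs


@dataclass(frozen=True)
class MAPEResult:
    """MAPE in percent plus the zero-hour exclusion bookkeeping."""

    value: float          # percent
    n_used: int           # E′ — hours entering the sum
    n_excluded: int       # observed-zero hours dropped

    def __float__(self) -> float:
        return self.value


def mape(observed: Sequence[float], simulated: Sequence[float]) -> MAPEResult:
    """Mean absolute percentage error, excluding observed-zero hours."""
    z, zs = _check_pair(observed, simulated)
    nonzero = z != 0
    n_used = int(nonzero.sum())
    if n_used == 0:
        raise UndefinedMetricError("MAPE undefined: every observation is zero")
    value = float(np.mean(np.abs(z[nonzero] - zs[nonzero]) / z[nonzero]) * 100.0)
    return MAPEResult(value=value, n_used=n_used, n_excluded=int(z.size - n_used))


def mae(observed: Sequence[float], simulated: Sequence[float]) -> float:
    """Mean absolute error, m³ h⁻¹."""
    z, zs = _check_pair(observed, simulated)
    return float(np.mean(np.abs(z - zs)))


def rmse(observed: Sequence[float], simulated: Sequence[float]) -> float:
    """Root mean squared error, m³ h⁻¹.  Always ≥ MAE on the same pair."""
    z, zs = _check_pair(observed, simulated)
    return float(np.sqrt(np.mean((z - zs) ** 2)))


@dataclass
class SimulationRun:
    """One rolling-origin run: fit at the origin, simulate H hours, score."""

    origin_index: int
    origin_time: object
    config: ModelConfig
    simulated: Optional[np.ndarray] = None
    observed: Optional[np.ndarray] = None
    mape: Optional[float] = None
    excluded_zero_hours: int = 0
    mae: Optional[float] = None
    rmse: Optional[float] = None
    model: Optional[FittedDLM] = None
    error: Optional[str] = None

    @property
    def ok(self) -> bool:
        return self.error is None


def count_origins(n: int, T: int, k: int, H: int, step: int = 24) -> int:
    """Closed-form number of valid rolling origins.

    The first origin needs T + k rows of history (training window plus
    warm-up) ending at the origin; every origin needs H rows of future.
    """
    if step < 1:
        raise BoundsError(f"step must be >= 1, got {step}")
    usable = n - (T + k) - H
    return 0 if usable < 0 else usable // step + 1


def rolling_evaluate(
    series: PlantSeries, config: ModelConfig, step: int = 24
) -> list[SimulationRun]:
    """Refit-and-simulate at every origin on the ``step``-hour grid.

    At each origin the model is fitted on the T observations ending there
    (with k warm-up rows before them) and an H-hour simulation is scored
    against the recorded production, with the recorded feeding standing in
    for the planned schedule.  Origins where the fit is singular, or where
    every observed hour is zero (downtime), are kept in the returned list as
    failed runs — they count, they just carry no metrics.
    """
    T, k, H = config.training_length, config.lag_order, config.horizon
    n = len(series)
    n_runs = count_origins(n, T, k, H, step)
    if n_runs == 0:
        raise EvaluationError(
            f"series of {n} rows supports no origin for T={T}, k={k}, H={H} "
            f"(needs at least {T + k + H} rows)"
        )

    runs: list[SimulationRun] = []
    first = T + k - 1
    for origin in range(first, first + n_runs * step, step):
        run = SimulationRun(
            origin_index=origin,
            origin_time=series.timestamps[origin],
            config=config,
        )
        observed = series.biogas[origin + 1 : origin + 1 + H].copy()
        planned = {
            r: series.regressor(r)[origin + 1 : origin + 1 + H] for r in config.regressors
        }
        history = {
            r: series.regressor(r)[origin + 1 - k : origin + 1] for r in config.regressors
        }
        try:
            model = fit_ols(build_design(series, config, origin))
            sim = simulate(model, planned, history)
            m = mape(observed, sim)
            run.model = model
            run.simulated = sim
            run.observed = observed
            run.mape = m.value
            run.excluded_zero_hours = m.n_excluded
            run.mae = mae(observed, sim)
            run.rmse = rmse(observed, sim)
        except (SingularDesignError, UndefinedMetricError) as exc:
            run.error = f"{type(exc).__name__}: {exc}"
            logger.warning("run at %s failed: %s", run.origin_time, run.error)
        runs.append(run)
    return runs


@dataclass
class EvaluationReport:
    """Mean per-run accuracy for every (T, k, H) cell of a settings grid."""

    digester_id: str
    table: pd.DataFrame  # long format: T, k, H, metric, value, n_runs, n_failed
    share_fits: bool

    def to_wide(self) -> pd.DataFrame:
        """Table-1-style layout: one row per (T, k), metric × H columns."""
        wide = self.table.pivot_table(
            index=["T", "k"], columns=["metric", "H"], values="value", sort=False
        )
        order = [
            (m, h)
            for m in ("MAPE", "RMSE", "MAE")
            for h in sorted(self.table["H"].unique())
            if (m, h) in wide.columns
        ]
        return wide.loc[:, order]


def _score_prefix(run: SimulationRun, H: int):
    obs, sim = run.observed[:H], run.simulated[:H]
    try:
        m = mape(obs, sim)
        return m.value, mae(obs, sim), rmse(obs, sim)
    except UndefinedMetricError:
        return None, mae(obs, sim), rmse(obs, sim)


def grid_report(
    series: PlantSeries,
    T_set: Sequence[int],
    k_set: Sequence[int],
    H_set: Sequence[int],
    step: int = 24,
    share_fits: bool = True,
    regressors: tuple = ("solid_feed",),
) -> EvaluationReport:
    """Mean MAPE/RMSE/MAE over the full settings grid.

    With ``share_fits`` (default) each (T, k) pair is rolled once at the
    maximal horizon and the smaller horizons are scored on prefixes of the
    same simulations; with ``share_fits=False`` every (T, k, H) cell gets an
    independent rolling evaluation (more runs for short horizons, unpaired
    columns).
    """
    if not (list(T_set) and list(k_set) and list(H_set)):
        raise EvaluationError("T_set, k_set and H_set must be nonempty")
    H_sorted = sorted(set(H_set))
    rows = []
    for T, k in itertools.product(T_set, k_set):
        if share_fits:
            config = ModelConfig(
                lag_order=k, training_length=T, horizon=H_sorted[-1], regressors=regressors
            )
            runs = rolling_evaluate(series, config, step)
            for H in H_sorted:
                rows.extend(_aggregate_cell(runs, T, k, H))
        else:
            for H in H_sorted:
                config = ModelConfig(
                    lag_order=k, training_length=T, horizon=H, regressors=regressors
                )
                runs = rolling_evaluate(series, config, step)
                rows.extend(_aggregate_cell(runs, T, k, H))
    return EvaluationReport(
        digester_id=series.digester_id,
        table=pd.DataFrame(rows),
        share_fits=share_fits,
    )


def _aggregate_cell(runs: list[SimulationRun], T: int, k: int, H: int) -> list[dict]:
    ok_runs = [r for r in runs if r.ok]
    n_failed = len(runs) - len(ok_runs)
    scores = {"MAPE": [], "MAE": [], "RMSE": []}
    for r in ok_runs:
        mp, ma, rm = _score_prefix(r, H)
        if mp is not None:
            scores["MAPE"].append(mp)
        scores["MAE"].append(ma)
        scores["RMSE"].append(rm)
    rows = []
    for metric, vals in scores.items():
        rows.append(
            {
                "T": T,
                "k": k,
                "H": H,
                "metric": metric,
                "value": float(np.mean(vals)) if vals else float("nan"),
                "n_runs": len(vals),
                "n_failed": n_failed,
            }
        )
    return rows
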