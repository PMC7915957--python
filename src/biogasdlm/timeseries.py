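"""Hourly plant time series: data model, validation, CSV I/O, windowing.

The central container is :class:`PlantSeries` — aligned hourly series of
substrate feeding (the regressors, kg h⁻¹) and biogas production at standard
conditions (the response, m³ h⁻¹).  All downstream stages (cross-correlation
screening, distributed-lag fitting, rolling evaluation, kinetics) operate on
this one type.

Timestamps are labels only: the model works on integer hour indices, and the
container guarantees a gap-free uniform 1-hour grid so positions and
timestamps are interchangeable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Optional, Union

import numpy as np
import pandas as pd

from .exceptions import BoundsError, GapError, SchemaError, ValidationError

__all__ = ["PlantSeries", "read_series", "write_series", "slice_window"]

logger = logging.getLogger(__name__)

#: canonical CSV column names
TIMESTAMP_COL = "timestamp"
SOLID_COL = "solid_feed_kg_h"
LIQUID_COL = "liquid_feed_kg_h"
BIOGAS_COL = "biogas_m3_h"

_ONE_HOUR = pd.Timedelta(hours=1)

Instant = Union[int, str, pd.Timestamp]


@dataclass
class PlantSeries:
    """Aligned hourly feeding/production series for one digester.

    Invariants (enforced on construction):

    * all series have the same length as ``timestamps``;
    * timestamps are strictly increasing with exactly 1 h spacing (no gaps);
    * all values are finite and non-negative — missing data must be repaired
      explicitly before a :class:`PlantSeries` can exist (see
      :func:`read_series`), never encoded as negative sentinels or NaN.
    """

    timestamps: pd.DatetimeIndex
    solid_feed: np.ndarray
    biogas: np.ndarray
    liquid_feed: Optional[np.ndarray] = None
    digester_id: str = "D1"

    def __post_init__(self) -> None:
        self.timestamps = pd.DatetimeIndex(self.timestamps)
        self.solid_feed = np.asarray(self.solid_feed, dtype=float)
        self.biogas = np.asarray(self.biogas, dtype=float)
        if self.liquid_feed is not None:
            self.liquid_feed = np.asarray(self.liquid_feed, dtype=float)

        n = len(self.timestamps)
        if n == 0:
            raise ValidationError("a PlantSeries must contain at least one row")
        for name, arr in self._arrays().items():
            if len(arr) != n:
                raise ValidationError(
                    f"{name} has length {len(arr)} but there are {n} timestamps"
                )

        if n > 1:
            diffs = np.diff(self.timestamps.asi8)
            bad = np.nonzero(diffs != _ONE_HOUR.value)[0]
            if bad.size:
                i = int(bad[0])
                raise GapError(
                    "timestamps must be strictly increasing on a uniform 1-hour "
                    f"grid; first offending interval "
                    f"{self.timestamps[i].isoformat()} -> "
                    f"{self.timestamps[i + 1].isoformat()}"
                )

        for name, arr in self._arrays().items():
            if not np.all(np.isfinite(arr)):
                i = int(np.nonzero(~np.isfinite(arr))[0][0])
                raise ValidationError(
                    f"{name} contains a missing/non-finite value at row {i} "
                    f"({self.timestamps[i].isoformat()}); repair explicitly "
                    "before constructing a PlantSeries"
                )
            if np.any(arr < 0):
                i = int(np.nonzero(arr < 0)[0][0])
                raise ValidationError(
                    f"{name} is negative ({arr[i]:g}) at row {i} "
                    f"({self.timestamps[i].isoformat()})"
                )

    # -- accessors ---------------------------------------------------------

    def _arrays(self) -> dict:
        out = {"solid_feed": self.solid_feed, "biogas": self.biogas}
        if self.liquid_feed is not None:
            out["liquid_feed"] = self.liquid_feed
        return out

    def __len__(self) -> int:
        return len(self.timestamps)

    @property
    def regressors(self) -> tuple:
        """Names of the feeding series available as model regressors."""
        return ("solid_feed",) + (("liquid_feed",) if self.liquid_feed is not None else ())

    def regressor(self, name: str) -> np.ndarray:
        if name == "solid_feed":
            return self.solid_feed
        if name == "liquid_feed":
            if self.liquid_feed is None:
                raise SchemaError("series has no liquid_feed regressor")
            return self.liquid_feed
        raise SchemaError(f"unknown regressor {name!r}; known: solid_feed, liquid_feed")

    def index_of(self, when: Instant) -> int:
        """Resolve an instant (timestamp or integer position) to a position."""
        if isinstance(when, (int, np.integer)):
            pos = int(when)
            if pos < 0:
                pos += len(self)
            if not 0 <= pos < len(self):
                raise BoundsError(f"position {when} outside series of length {len(self)}")
            return pos
        ts = pd.Timestamp(when)
        try:
            return int(self.timestamps.get_loc(ts))
        except KeyError:
            raise BoundsError(
                f"{ts.isoformat()} not in series span "
                f"[{self.timestamps[0].isoformat()}, {self.timestamps[-1].isoformat()}]"
            ) from None

    def islice(self, start: int, stop: int) -> "PlantSeries":
        """Positional half-open slice returning a new PlantSeries."""
        return replace(
            self,
            timestamps=self.timestamps[start:stop],
            solid_feed=self.solid_feed[start:stop],
            biogas=self.biogas[start:stop],
            liquid_feed=None if self.liquid_feed is None else self.liquid_feed[start:stop],
        )

    def to_frame(self) -> pd.DataFrame:
        data = {TIMESTAMP_COL: self.timestamps, SOLID_COL: self.solid_feed}
        if self.liquid_feed is not None:
            data[LIQUID_COL] = self.liquid_feed
        data[BIOGAS_COL] = self.biogas
        return pd.DataFrame(data)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, PlantSeries):
            return NotImplemented
        if len(self) != len(other) or not self.timestamps.equals(other.timestamps):
            return False
        if (self.liquid_feed is None) != (other.liquid_feed is None):
            return False
        same = np.array_equal(self.solid_feed, other.solid_feed) and np.array_equal(
            self.biogas, other.biogas
        )
        if self.liquid_feed is not None:
            same = same and np.array_equal(self.liquid_feed, other.liquid_feed)
        return same


def read_series(
    path: Union[str, Path],
    column_map: Optional[Mapping[str, str]] = None,
    repair: bool = False,
    digester_id: Optional[str] = None,
) -> PlantSeries:
    """Read and validate an hourly plant CSV.

    Parameters
    ----------
    path
        CSV with a header row; must provide a timestamp column, a solid-feed
        column and a biogas column (liquid feed optional).
    column_map
        Mapping from canonical names (``timestamp``, ``solid_feed_kg_h``,
        ``liquid_feed_kg_h``, ``biogas_m3_h``) to the names actually used in
        the file.  Canonical names are assumed where the map is silent.
    repair
        If True, repair missing values before validation: feeding gaps are
        forward-filled (a feeding sensor holds its last reading; leading gaps
        become 0) and biogas gaps are linearly interpolated.  OFF by default —
        silent imputation would corrupt fits — and logged when it changes
        anything.
    """
    column_map = dict(column_map or {})
    df = pd.read_csv(path, float_precision="round_trip")

    def col(canonical: str) -> str:
        return column_map.get(canonical, canonical)

    for canonical in (TIMESTAMP_COL, SOLID_COL, BIOGAS_COL):
        if col(canonical) not in df.columns:
            raise SchemaError(
                f"required column {col(canonical)!r} (for {canonical}) missing "
                f"from {path}; found {list(df.columns)}"
            )
    has_liquid = col(LIQUID_COL) in df.columns

    ts = pd.to_datetime(df[col(TIMESTAMP_COL)], format="ISO8601")
    if ts.duplicated().any():
        dup = ts[ts.duplicated()].iloc[0]
        raise ValidationError(f"duplicate timestamp {dup.isoformat()} in {path}")
    order = np.argsort(ts.to_numpy())
    df = df.iloc[order].reset_index(drop=True)
    ts = pd.DatetimeIndex(ts.to_numpy()[order])

    solid = pd.to_numeric(df[col(SOLID_COL)], errors="coerce")
    biogas = pd.to_numeric(df[col(BIOGAS_COL)], errors="coerce")
    liquid = pd.to_numeric(df[col(LIQUID_COL)], errors="coerce") if has_liquid else None

    if repair:
        for name, series_ in [("solid_feed", solid)] + (
            [("liquid_feed", liquid)] if liquid is not None else []
        ):
            n_missing = int(series_.isna().sum())
            if n_missing:
                series_.ffill(inplace=True)
                series_.fillna(0.0, inplace=True)
                logger.warning(
                    "repair: forward-filled %d missing %s values in %s",
                    n_missing, name, path,
                )
        n_missing = int(biogas.isna().sum())
        if n_missing:
            biogas.interpolate(method="linear", limit_direction="both", inplace=True)
            logger.warning(
                "repair: interpolated %d missing biogas values in %s", n_missing, path
            )

    return PlantSeries(
        timestamps=ts,
        solid_feed=solid.to_numpy(),
        biogas=biogas.to_numpy(),
        liquid_feed=None if liquid is None else liquid.to_numpy(),
        digester_id=digester_id or "D1",
    )


def write_series(series: PlantSeries, path: Union[str, Path]) -> None:
    """Write a PlantSeries as canonical CSV (ISO-8601 stamps, '.' decimals).

    Floats are written with full round-trip precision so that
    ``read_series(write_series(s)) == s`` exactly.
    """
    df = series.to_frame()
    df[TIMESTAMP_COL] = df[TIMESTAMP_COL].dt.strftime("%Y-%m-%dT%H:%M:%S")
    # %.17g guarantees bit-exact float round-trips through the CSV
    df.to_csv(path, index=False, float_format="%.17g")


def slice_window(
    series: PlantSeries, end: Instant, length: int, warmup: int = 0
) -> PlantSeries:
    """Sub-series of ``length`` rows ending at ``end`` plus ``warmup`` leading rows.

    The warm-up rows exist so that every one of the ``length`` training rows
    has all its lagged regressor values observed (no implicit zero padding):
    a training window of T observations for a lag-k model is requested as
    ``slice_window(s, end, length=T, warmup=k)`` and always yields exactly
    T + k rows or raises.
    """
    if length < 1 or warmup < 0:
        raise BoundsError(f"need length >= 1 and warmup >= 0, got {length}, {warmup}")
    end_pos = series.index_of(end)
    start = end_pos - (length + warmup) + 1
    if start < 0:
        raise BoundsError(
            f"window of {length}+{warmup} rows ending at position {end_pos} needs "
            f"{length + warmup} rows of history but only {end_pos + 1} are available"
        )
    return series.islice(start, end_pos + 1)
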