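"""Time-series container and CSV I/O for wearable light-logger data.

The central object is :class:`LightTimeSeries`: timestamped melanopic
equivalent daylight illuminance (mel EDI, lux) samples with a source label
distinguishing the wearer ("participant") from a stationary reference
sensor ("environment").  Values are nonnegative and zero-inflated: light
below the device's detection floor is recorded as exactly 0 lux.  Missing
values (NaN) are representable and deliberately distinct from 0 lux — one
of the zero-handling strategies converts zeros to missing, and the two
states must never be conflated.

CSV files follow the LightLogR dialect: columns ``Datetime`` (ISO 8601,
timezone-naive local wall-clock time), ``MEDI`` (lux, empty field =
missing) and ``Id`` (source label).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "LightTimeSeries",
    "DayWindow",
    "ValidationError",
    "FormatError",
    "read_series",
    "write_series",
    "split_day_night",
]

DEFAULT_COLUMNS = {"timestamp": "Datetime", "medi": "MEDI", "source": "Id"}


class ValidationError(ValueError):
    """A series violates a LightTimeSeries invariant."""


class FormatError(ValueError):
    """An input file does not match the expected CSV dialect."""


@dataclass
class LightTimeSeries:
    """Regularly sampled, nonnegative, zero-inflated illuminance series.

    Parameters
    ----------
    timestamps
        Timezone-naive local datetimes, one per sample.
    medi
        Melanopic EDI in lux, ``>= 0``; NaN marks a missing sample.
    source
        Per-sample label from a finite set (typically ``participant`` /
        ``environment``).  A single string is broadcast to all samples.
    interval
        Sampling interval in seconds.  Inferred from the timestamps when
        omitted.

    Invariants (checked on construction): non-missing values are
    nonnegative; within each source label, timestamps are strictly
    increasing with constant spacing equal to ``interval``.
    """

    timestamps: pd.DatetimeIndex
    medi: np.ndarray
    source: np.ndarray
    interval: float = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.timestamps = pd.DatetimeIndex(self.timestamps)
        self.medi = np.asarray(self.medi, dtype=float)
        if np.ndim(self.source) == 0:
            self.source = np.full(len(self.timestamps), str(self.source), dtype=object)
        else:
            self.source = np.asarray(self.source, dtype=object)
        n = len(self.timestamps)
        if len(self.medi) != n or len(self.source) != n:
            raise ValidationError(
                f"length mismatch: {n} timestamps, {len(self.medi)} values, "
                f"{len(self.source)} source labels"
            )
        finite = self.medi[~np.isnan(self.medi)]
        if finite.size and (bad := np.flatnonzero(~np.isnan(self.medi) & (self.medi < 0))).size:
            raise ValidationError(
                f"negative illuminance at row {bad[0]}: {self.medi[bad[0]]!r} lux"
            )
        inferred = None
        for label in self.sources:
            t = self.timestamps[self.source == label].asi8 / 1e9
            if len(t) < 2:
                continue
            dt = np.diff(t)
            if np.any(dt <= 0):
                row = int(np.flatnonzero(dt <= 0)[0]) + 1
                raise ValidationError(
                    f"timestamps for source {label!r} not strictly increasing "
                    f"at position {row}"
                )
            if not np.allclose(dt, dt[0], rtol=0, atol=1e-6):
                row = int(np.flatnonzero(~np.isclose(dt, dt[0], rtol=0, atol=1e-6))[0]) + 1
                raise ValidationError(
                    f"irregular sampling for source {label!r} at position {row}: "
                    f"step {dt[np.flatnonzero(~np.isclose(dt, dt[0]))[0]]:.6g} s "
                    f"!= {dt[0]:.6g} s"
                )
            inferred = dt[0] if inferred is None else inferred
        if self.interval is None:
            self.interval = float(inferred) if inferred is not None else 0.0
        elif inferred is not None and not np.isclose(self.interval, inferred):
            raise ValidationError(
                f"declared interval {self.interval} s != observed spacing {inferred} s"
            )
        self.interval = float(self.interval)

    def __len__(self) -> int:
        return len(self.timestamps)

    @property
    def sources(self) -> list[str]:
        """Distinct source labels, in order of first appearance."""
        return list(dict.fromkeys(self.source))

    def select(self, mask: np.ndarray) -> "LightTimeSeries":
        """Subset by boolean mask, bypassing the regular-spacing check."""
        obj = object.__new__(LightTimeSeries)
        obj.timestamps = self.timestamps[mask]
        obj.medi = self.medi[mask]
        obj.source = self.source[mask]
        obj.interval = self.interval
        return obj

    def for_source(self, label: str) -> "LightTimeSeries":
        """Sub-series holding a single source label."""
        if label not in self.sources:
            raise KeyError(f"unknown source {label!r}; have {self.sources}")
        return self.select(self.source == label)

    def with_values(self, medi: np.ndarray) -> "LightTimeSeries":
        """Copy of the series with replaced lux values."""
        return LightTimeSeries(self.timestamps, np.asarray(medi, float),
                               self.source.copy(), self.interval)

    def seconds_from_midnight(self) -> np.ndarray:
        """Clock time of each sample in seconds since local midnight."""
        t = self.timestamps
        return (t.hour * 3600 + t.minute * 60 + t.second
                + t.microsecond / 1e6).to_numpy(float)

    def to_frame(self, columns: dict[str, str] | None = None) -> pd.DataFrame:
        cols = {**DEFAULT_COLUMNS, **(columns or {})}
        return pd.DataFrame({
            cols["timestamp"]: self.timestamps,
            cols["medi"]: self.medi,
            cols["source"]: self.source,
        })


@dataclass(frozen=True)
class DayWindow:
    """Civil dawn/dusk pair partitioning a day into daytime and nighttime.

    Daytime is the half-open interval ``[dawn, dusk)``; everything else is
    nighttime, so the partition is exhaustive and never double-counts a
    sample that falls exactly on a boundary.
    """

    dawn: pd.Timestamp
    dusk: pd.Timestamp

    def __post_init__(self) -> None:
        object.__setattr__(self, "dawn", pd.Timestamp(self.dawn))
        object.__setattr__(self, "dusk", pd.Timestamp(self.dusk))
        if not self.dawn < self.dusk:
            raise ValidationError(f"dawn {self.dawn} must precede dusk {self.dusk}")


def read_series(path, columns: dict[str, str] | None = None) -> LightTimeSeries:
    """Read a LightTimeSeries from a LightLogR-dialect CSV file.

    ``columns`` remaps the logical names ``timestamp``/``medi``/``source``
    onto the file's header (defaults ``Datetime``/``MEDI``/``Id``).  A
    missing ``source`` column yields the label ``"participant"`` for every
    row.  Rows violating the invariants raise :class:`ValidationError`
    naming the first offending row rather than being silently dropped.
    """
    cols = {**DEFAULT_COLUMNS, **(columns or {})}
    df = pd.read_csv(path, float_precision="round_trip")
    for key in ("timestamp", "medi"):
        if cols[key] not in df.columns:
            raise FormatError(
                f"column {cols[key]!r} (for {key}) not in {list(df.columns)}"
            )
    try:
        ts = pd.to_datetime(df[cols["timestamp"]], format="ISO8601")
    except (ValueError, TypeError) as exc:
        raise FormatError(f"timestamp column does not parse as ISO 8601: {exc}") from exc
    medi = pd.to_numeric(df[cols["medi"]], errors="coerce").to_numpy(float)
    non_numeric = df[cols["medi"]].notna() & np.isnan(medi)
    if non_numeric.any():
        row = int(np.flatnonzero(non_numeric)[0])
        raise FormatError(
            f"non-numeric lux value {df[cols['medi']].iloc[row]!r} at row {row}"
        )
    if cols["source"] in df.columns:
        source = df[cols["source"]].astype(str).to_numpy(object)
    else:
        source = np.full(len(df), "participant", dtype=object)
    return LightTimeSeries(pd.DatetimeIndex(ts), medi, source)


def write_series(series: LightTimeSeries, path,
                 columns: dict[str, str] | None = None) -> None:
    """Write a series as CSV so that :func:`read_series` roundtrips exactly.

    Timestamps are written as ISO 8601 to the second; lux values keep full
    double precision (``repr`` formatting); missing values become empty
    fields.
    """
    df = series.to_frame(columns)
    ts_col, medi_col = df.columns[0], df.columns[1]
    df[ts_col] = df[ts_col].dt.strftime("%Y-%m-%dT%H:%M:%S")
    df[medi_col] = [
        "" if np.isnan(v) else np.format_float_positional(v, unique=True, trim="0")
        for v in df[medi_col]
    ]
    df.to_csv(path, index=False)


def split_day_night(series: LightTimeSeries, window: DayWindow
                    ) -> tuple[LightTimeSeries, LightTimeSeries]:
    """Partition samples into (daytime, nighttime) by a civil dawn/dusk window.

    Daytime is ``dawn <= t < dusk``.  The two subsets are disjoint and
    exhaustive.  A window entirely outside the series range produces an
    empty daytime subset and a warning.
    """
    t = series.timestamps
    day_mask = (t >= window.dawn) & (t < window.dusk)
    if len(series) and not day_mask.any():
        warnings.warn(
            f"day window [{window.dawn}, {window.dusk}) contains no samples "
            f"of series spanning [{t.min()}, {t.max()}]", stacklevel=2)
    return series.select(day_mask), series.select(~day_mask)
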