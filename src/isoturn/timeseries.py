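"""Data model and CSV I/O for delta13C time series.

All times are hours relative to the diet switch (t = 0): equilibration
samples are negative, chase samples positive.  Isotope values are per mil
(permil) vs. VPDB.  The on-disk format is a long CSV with columns
``animal_id,stream,time_h,delta13C``; lines starting with ``#`` are comments.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Iterator

import numpy as np
import pandas as pd

__all__ = [
    "STREAMS",
    "IsotopeSample",
    "IsotopeSeries",
    "StudyDataset",
    "FormatError",
    "read_series_csv",
    "write_series_csv",
    "resample_to_grid",
]

#: Conventional stream labels; arbitrary custom labels are also accepted.
STREAMS = ("diet", "whole_milk", "lactose", "casein", "milk_fat", "feces")

CSV_COLUMNS = ["animal_id", "stream", "time_h", "delta13C"]


class FormatError(ValueError):
    """Malformed input data (missing columns, bad values, duplicates)."""


@dataclass(frozen=True)
class IsotopeSample:
    """A single delta13C measurement of one stream of one animal."""

    animal_id: str
    stream: str
    time_h: float
    delta13C: float

    def __post_init__(self):
        if not self.stream:
            raise ValueError("stream label must be nonempty")
        if not math.isfinite(self.time_h):
            raise ValueError("time_h must be finite")
        if not math.isfinite(self.delta13C):
            raise ValueError("delta13C must be finite")


class IsotopeSeries:
    """Time-ordered delta13C course of one stream for one animal.

    Parameters
    ----------
    animal_id, stream : str
        Identify the series.
    times_h, values : array-like
        Sample times (hours relative to the switch) and delta13C (permil).
        Times must be strictly increasing; unsorted input is sorted.
    """

    def __init__(self, animal_id: str, stream: str, times_h, values):
        t = np.asarray(times_h, dtype=float)
        v = np.asarray(values, dtype=float)
        if t.ndim != 1 or t.shape != v.shape:
            raise ValueError("times_h and values must be 1-D and equal length")
        if t.size < 1:
            raise ValueError("a series needs at least one sample")
        if not (np.isfinite(t).all() and np.isfinite(v).all()):
            raise ValueError("times and values must be finite")
        order = np.argsort(t, kind="stable")
        t, v = t[order], v[order]
        if np.any(np.diff(t) <= 0):
            dup = t[:-1][np.diff(t) <= 0]
            raise FormatError(
                f"duplicate timestamp(s) in series ({animal_id}, {stream}): "
                f"{dup[:5].tolist()}"
            )
        if not stream:
            raise ValueError("stream label must be nonempty")
        self.animal_id = str(animal_id)
        self.stream = str(stream)
        self.times_h = t
        self.values = v

    def __len__(self) -> int:
        return self.times_h.size

    def __iter__(self) -> Iterator[tuple[float, float]]:
        return iter(zip(self.times_h.tolist(), self.values.tolist()))

    def __repr__(self) -> str:
        return (
            f"IsotopeSeries({self.animal_id!r}, {self.stream!r}, "
            f"n={len(self)}, t=[{self.times_h[0]:g}, {self.times_h[-1]:g}] h)"
        )

    def samples(self) -> list[IsotopeSample]:
        return [
            IsotopeSample(self.animal_id, self.stream, t, v) for t, v in self
        ]

    def slice_time(self, t_min=-np.inf, t_max=np.inf) -> "IsotopeSeries":
        """Sub-series with t_min <= time <= t_max."""
        m = (self.times_h >= t_min) & (self.times_h <= t_max)
        if not m.any():
            raise ValueError("no samples in the requested time window")
        return IsotopeSeries(
            self.animal_id, self.stream, self.times_h[m], self.values[m]
        )

    def value_at(self, t: float, method: str = "previous") -> float:
        """Interpolated value at time ``t`` (no extrapolation beyond range)."""
        if t < self.times_h[0] or t > self.times_h[-1]:
            raise ValueError(
                f"time {t} h outside series range "
                f"[{self.times_h[0]}, {self.times_h[-1]}] h"
            )
        return float(_interp(self.times_h, self.values, np.array([t]), method)[0])


def _interp(t, v, grid, method):
    if method == "previous":
        idx = np.searchsorted(t, grid, side="right") - 1
        idx = np.clip(idx, 0, t.size - 1)
        return v[idx]
    if method == "linear":
        return np.interp(grid, t, v)
    raise ValueError(f"unknown resampling method {method!r}")


def resample_to_grid(
    series: IsotopeSeries, step_h: float, method: str = "previous"
) -> IsotopeSeries:
    """Resample onto a regular grid from first to last sample time inclusive.

    ``previous`` carries the last observed value forward (the natural
    dialect for batch-fed diet input); ``linear`` interpolates.  Endpoints
    always equal the original endpoint values.  A single-sample series is
    returned unchanged.
    """
    if step_h <= 0:
        raise ValueError("step_h must be positive")
    t0, t1 = series.times_h[0], series.times_h[-1]
    if len(series) == 1 or t1 == t0:
        return IsotopeSeries(
            series.animal_id, series.stream, series.times_h[:1], series.values[:1]
        )
    n = int(math.floor((t1 - t0) / step_h + 1e-9))
    grid = t0 + step_h * np.arange(n + 1)
    if grid[-1] < t1 - 1e-9 * max(1.0, abs(t1)):
        grid = np.append(grid, t1)
    else:
        grid[-1] = t1  # guard accumulated float error
    vals = _interp(series.times_h, series.values, grid, method)
    return IsotopeSeries(series.animal_id, series.stream, grid, vals)


@dataclass
class StudyDataset:
    """All series of one diet-switch study, keyed by (animal_id, stream)."""

    series: dict[tuple[str, str], IsotopeSeries] = field(default_factory=dict)
    switch_time_h: float = 0.0
    metadata: dict = field(default_factory=dict)

    def add(self, s: IsotopeSeries) -> None:
        key = (s.animal_id, s.stream)
        if key in self.series:
            raise FormatError(f"duplicate series for {key}")
        self.series[key] = s

    def __len__(self) -> int:
        return len(self.series)

    def animals(self) -> list[str]:
        return sorted({a for a, _ in self.series})

    def streams(self) -> list[str]:
        return sorted({s for _, s in self.series})

    def get(self, animal_id: str, stream: str) -> IsotopeSeries:
        return self.series[(str(animal_id), str(stream))]

    def stream_series(self, stream: str) -> list[IsotopeSeries]:
        """All animals' series for one stream, sorted by animal id."""
        out = [s for (a, st), s in sorted(self.series.items()) if st == stream]
        if not out:
            raise KeyError(f"no series for stream {stream!r}")
        return out

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for (a, st), s in sorted(self.series.items()):
            rows.append(
                pd.DataFrame(
                    {
                        "animal_id": a,
                        "stream": st,
                        "time_h": s.times_h,
                        "delta13C": s.values,
                    }
                )
            )
        if not rows:
            return pd.DataFrame(columns=CSV_COLUMNS)
        return pd.concat(rows, ignore_index=True)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, **meta) -> "StudyDataset":
        missing = [c for c in CSV_COLUMNS if c not in df.columns]
        if missing:
            raise FormatError(f"missing required column(s): {', '.join(missing)}")
        for col in ("time_h", "delta13C"):
            vals = pd.to_numeric(df[col], errors="coerce")
            bad = df.index[vals.isna() & df[col].notna()]
            if len(bad):
                raise FormatError(
                    f"non-numeric {col} at row {int(bad[0]) + 2}"  # 1-based + header
                )
            if vals.isna().any():
                raise FormatError(f"missing {col} value")
            df = df.assign(**{col: vals})
        ds = cls(metadata=dict(meta))
        for (a, st), g in df.groupby(["animal_id", "stream"], sort=True):
            ds.add(IsotopeSeries(str(a), str(st), g["time_h"], g["delta13C"]))
        return ds


def read_series_csv(path) -> StudyDataset:
    """Read a long-format study CSV (see module docstring for the schema)."""
    df = pd.read_csv(path, comment="#", dtype={"animal_id": str, "stream": str})
    return StudyDataset.from_frame(df)


def write_series_csv(data: StudyDataset, path) -> None:
    """Write a StudyDataset as long CSV; inverse of :func:`read_series_csv`."""
    df = data.to_frame()
    df.to_csv(path, index=False, float_format="%.9g")
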