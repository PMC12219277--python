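"""Core domain types: sensor series, 3-day analysis windows, interval groupings.

A :class:`HiveSeries` holds one hive's temperature or CO2 trace on a regular
sampling grid (5, 15 or 30 min).  Missing stretches are represented in-grid as
NaN values carrying a ``gap`` flag, so every downstream stage sees a uniform
time base and can decide for itself how to treat holes.  The unit of all
rhythm fitting is the :class:`SubsetWindow`, a contiguous 72 h slice of a
detrended series.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

VALID_VARIABLES = ("temperature", "co2")
VALID_SITES = ("CSU", "outside")
VALID_INTERVALS_MIN = (5, 15, 30)

#: point flags
FLAG_OBSERVED = "observed"
FLAG_INTERPOLATED = "interpolated"
FLAG_GAP = "gap"


class ValidationError(ValueError):
    """Raised when a series violates a structural invariant."""


@dataclass
class HiveSeries:
    """One hive's timestamped sensor trace plus metadata.

    Parameters
    ----------
    hive_id : str
        Opaque hive label.
    variable : {"temperature", "co2"}
        Measured quantity (degC or % concentration).
    site : {"CSU", "outside"}
        Cold-storage unit or ambient apiary.
    experiment : str
        Opaque experiment label.
    timestamps : pandas.DatetimeIndex
        Strictly increasing, timezone-naive local clock time, regular at
        ``sampling_interval`` minutes.
    values : numpy.ndarray
        Sensor readings; NaN at gap positions.
    sampling_interval : int
        Minutes between consecutive samples (5, 15 or 30).
    flags : numpy.ndarray of str
        Per-point provenance: ``observed`` / ``interpolated`` / ``gap``.
    """

    hive_id: str
    variable: str
    site: str
    experiment: str
    timestamps: pd.DatetimeIndex
    values: np.ndarray
    sampling_interval: int
    flags: np.ndarray = field(default=None)  # type: ignore[assignment]
    #: residual series (after detrending); unit-level invariants like
    #: CO2 >= 0 apply only to raw concentrations
    detrended: bool = False

    def __post_init__(self) -> None:
        if self.variable not in VALID_VARIABLES:
            raise ValidationError(
                f"variable must be one of {VALID_VARIABLES}, got {self.variable!r}"
            )
        if self.site not in VALID_SITES:
            raise ValidationError(f"site must be one of {VALID_SITES}, got {self.site!r}")
        self.timestamps = pd.DatetimeIndex(self.timestamps)
        self.values = np.asarray(self.values, dtype=float)
        if len(self.timestamps) != len(self.values):
            raise ValidationError("timestamps and values differ in length")
        if len(self.timestamps) >= 2:
            diffs = np.diff(self.timestamps.asi8)
            if np.any(diffs <= 0):
                raise ValidationError("timestamps must be strictly increasing")
            step = np.timedelta64(int(self.sampling_interval), "m").astype(
                "timedelta64[ns]"
            ).astype(np.int64)
            if np.any(diffs != step):
                raise ValidationError(
                    "timestamps are not on a regular "
                    f"{self.sampling_interval}-min grid; regularize() first"
                )
        if self.flags is None:
            self.flags = np.where(
                np.isfinite(self.values), FLAG_OBSERVED, FLAG_GAP
            ).astype(object)
        else:
            self.flags = np.asarray(self.flags, dtype=object)
            if len(self.flags) != len(self.values):
                raise ValidationError("flags and values differ in length")
        observed = self.flags != FLAG_GAP
        if not np.all(np.isfinite(self.values[observed])):
            raise ValidationError("non-gap values must be finite")
        if self.variable == "co2" and not self.detrended and np.any(self.values[observed] < 0):
            raise ValidationError("CO2 concentrations must be >= 0")

    # -- convenience -------------------------------------------------------
    def __len__(self) -> int:
        return len(self.values)

    @property
    def hours(self) -> np.ndarray:
        """Hours elapsed since the first sample."""
        return (self.timestamps.asi8 - self.timestamps.asi8[0]) / 3.6e12

    @property
    def hours_since_midnight(self) -> np.ndarray:
        """Hours since local midnight of the first sample's calendar day.

        This is the common angular reference that makes acrophases
        comparable across subsets and hives.
        """
        midnight = self.timestamps[0].normalize()
        return (self.timestamps.asi8 - midnight.value) / 3.6e12

    @property
    def duration_hours(self) -> float:
        if len(self) < 2:
            return 0.0
        return float(self.hours[-1]) + self.sampling_interval / 60.0

    @property
    def n_gaps(self) -> int:
        return int(np.sum(self.flags == FLAG_GAP))

    def slice_hours(self, start_h: float, end_h: float) -> "HiveSeries":
        """Return the sub-series with first-sample-relative hours in [start_h, end_h)."""
        h = self.hours
        mask = (h >= start_h - 1e-9) & (h < end_h - 1e-9)
        if not mask.any():
            raise ValidationError(f"empty slice [{start_h}, {end_h}) h")
        return replace(
            self,
            timestamps=self.timestamps[mask],
            values=self.values[mask],
            flags=self.flags[mask],
        )

    def with_values(self, values: np.ndarray, flags: np.ndarray | None = None) -> "HiveSeries":
        return replace(
            self,
            values=np.asarray(values, dtype=float),
            flags=self.flags.copy() if flags is None else flags,
        )


@dataclass
class SubsetWindow:
    """A contiguous 72 h slice of a detrended series — the unit of fitting.

    ``index`` is 1-based (1..6 for the fall experiments, 1..8 or more for the
    phase experiments).  ``values`` are detrended residuals.
    """

    parent: HiveSeries
    index: int
    timestamps: pd.DatetimeIndex
    values: np.ndarray
    sampling_interval: int
    flags: np.ndarray

    def __len__(self) -> int:
        return len(self.values)

    @property
    def has_gaps(self) -> bool:
        return bool(np.any(self.flags == FLAG_GAP) or np.any(~np.isfinite(self.values)))

    @property
    def hours_since_midnight(self) -> np.ndarray:
        midnight = self.timestamps[0].normalize()
        return (self.timestamps.asi8 - midnight.value) / 3.6e12

    @property
    def hive_id(self) -> str:
        return self.parent.hive_id


@dataclass(frozen=True)
class Interval:
    """A labelled pooling of exactly two consecutive 3-d subsets per hive."""

    label: str
    subset_indices: tuple[int, int]
    regime: str  # dark | light12 | ambient

    def __post_init__(self) -> None:
        i, j = self.subset_indices
        if j != i + 1:
            raise ValidationError(
                f"interval {self.label!r} must pool two consecutive subsets, got {self.subset_indices}"
            )
        if self.regime not in ("dark", "light12", "ambient"):
            raise ValidationError(f"unknown regime {self.regime!r}")


def regularize(series: HiveSeries, max_gap: float = 60.0) -> HiveSeries:
    """Snap a series onto its full regular grid, filling single missing points.

    A hole of exactly one sample (timestamp gap of twice the sampling
    interval) is filled by linear interpolation and flagged ``interpolated``.
    Longer holes, up to any length, become in-grid NaN runs flagged ``gap``;
    ``max_gap`` (minutes) is retained for API symmetry — runs longer than one
    point are never interpolated regardless of its value.
    """
    ts = series.timestamps
    step = pd.Timedelta(minutes=series.sampling_interval)
    full = pd.date_range(ts[0], ts[-1], freq=step)
    ser = pd.Series(series.values, index=ts).reindex(full)
    flags = pd.Series(series.flags, index=ts).reindex(full, fill_value=FLAG_GAP).to_numpy()

    vals = ser.to_numpy()
    missing = ~np.isfinite(vals)
    # single isolated holes -> linear midpoint
    for i in np.flatnonzero(missing):
        if 0 < i < len(vals) - 1 and np.isfinite(vals[i - 1]) and np.isfinite(vals[i + 1]):
            vals[i] = 0.5 * (vals[i - 1] + vals[i + 1])
            flags[i] = FLAG_INTERPOLATED
    return replace(series, timestamps=full, values=vals, flags=flags)


def count_gap_runs(series: HiveSeries) -> int:
    """Number of maximal contiguous runs of gap-flagged points."""
    gap = (series.flags == FLAG_GAP).astype(int)
    if gap.sum() == 0:
        return 0
    starts = np.flatnonzero(np.diff(np.concatenate([[0], gap])) == 1)
    return len(starts)


def split_subsets(
    series: HiveSeries, n_subsets: int, subset_hours: float = 72.0
) -> list[SubsetWindow]:
    """Cut a (detrended) series into contiguous non-overlapping 72 h windows.

    Windows start at the series' first timestamp.  Raises if the series is
    shorter than ``n_subsets * subset_hours``.
    """
    pts_per = int(round(subset_hours * 60.0 / series.sampling_interval))
    needed = n_subsets * pts_per
    if len(series) < needed:
        have_h = len(series) * series.sampling_interval / 60.0
        raise ValidationError(
            f"series covers {have_h:.1f} h but {n_subsets}x{subset_hours:.0f} h "
            f"= {n_subsets * subset_hours:.0f} h required"
        )
    out = []
    for k in range(n_subsets):
        sl = slice(k * pts_per, (k + 1) * pts_per)
        out.append(
            SubsetWindow(
                parent=series,
                index=k + 1,
                timestamps=series.timestamps[sl],
                values=series.values[sl],
                sampling_interval=series.sampling_interval,
                flags=series.flags[sl],
            )
        )
    return out


def subsets_for_days(
    series: HiveSeries,
    day_ranges: Sequence[tuple[float, float]],
    origin: pd.Timestamp | None = None,
) -> list[SubsetWindow]:
    """Extract 3-d windows at absolute day offsets from ``origin``.

    ``day_ranges`` use 1-based inclusive day labels as in experiment designs
    ("days 7-12" means two 3-d windows covering hours [144, 288) from the
    experiment start).  ``origin`` defaults to midnight of the series' first
    day.  Each (d0, d1) range is cut into consecutive 72 h windows.
    """
    if origin is None:
        origin = series.timestamps[0].normalize()
    out: list[SubsetWindow] = []
    idx = 0
    offset_h = (series.timestamps[0].value - origin.value) / 3.6e12
    for d0, d1 in day_ranges:
        start_h = (d0 - 1) * 24.0 - offset_h
        end_h = d1 * 24.0 - offset_h
        n_win = int(round((end_h - start_h) / 72.0))
        for k in range(n_win):
            idx += 1
            sub = series.slice_hours(start_h + 72.0 * k, start_h + 72.0 * (k + 1))
            out.append(
                SubsetWindow(
                    parent=series,
                    index=idx,
                    timestamps=sub.timestamps,
                    values=sub.values,
                    sampling_interval=series.sampling_interval,
                    flags=sub.flags,
                )
            )
    return out
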