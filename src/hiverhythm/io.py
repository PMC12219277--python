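"""Reading and writing sensor-log CSVs.

Input format: a header row then ``timestamp,value`` records with ISO-8601
timestamps and float values.  Output mirrors the input with an added ``flag``
column (``observed`` / ``interpolated`` / ``gap``); gap rows carry an empty
value field.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .core import (
    FLAG_GAP,
    FLAG_OBSERVED,
    HiveSeries,
    ValidationError,
)


def load_series(
    path: str | Path,
    hive_id: str,
    variable: str,
    site: str = "CSU",
    experiment: str = "unspecified",
    sampling_interval: int | None = None,
) -> HiveSeries:
    """Read one hive's sensor log into a validated :class:`HiveSeries`.

    Rows are sorted by timestamp; duplicated timestamps are rejected.  Missing
    rows (judged against the sampling interval, inferred from the modal
    timestamp difference when not given) become in-grid gap points so the
    returned series always sits on a regular grid.

    Raises
    ------
    ValidationError
        On malformed timestamps (naming the offending row), duplicates, or
        an off-grid timestamp.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    cols = {c.lower().strip(): c for c in df.columns}
    if "timestamp" not in cols or "value" not in cols:
        raise ValidationError(
            f"{path}: expected columns 'timestamp' and 'value', found {list(df.columns)}"
        )
    raw_ts = df[cols["timestamp"]]
    ts = pd.to_datetime(raw_ts, format="ISO8601", errors="coerce")
    bad = ts.isna() & raw_ts.notna()
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0])
        raise ValidationError(
            f"{path}: cannot parse timestamp {raw_ts.iloc[row]!r} at data row {row + 1}"
        )
    values = pd.to_numeric(df[cols["value"]], errors="coerce").to_numpy(dtype=float)
    flags = None
    if "flag" in cols:
        flags = df[cols["flag"]].fillna(FLAG_GAP).to_numpy(dtype=object)

    order = np.argsort(ts.to_numpy(), kind="stable")
    ts = pd.DatetimeIndex(ts.to_numpy()[order])
    values = values[order]
    if flags is not None:
        flags = flags[order]
    if ts.has_duplicates:
        dup = ts[ts.duplicated()][0]
        raise ValidationError(f"{path}: duplicate timestamp {dup}")

    if sampling_interval is None:
        diffs = np.diff(ts.asi8) // 60_000_000_000
        if len(diffs) == 0:
            raise ValidationError(f"{path}: need at least two rows to infer interval")
        vals_, counts = np.unique(diffs, return_counts=True)
        sampling_interval = int(vals_[np.argmax(counts)])

    # snap onto the full regular grid; absent rows become gap points
    step = pd.Timedelta(minutes=sampling_interval)
    full = pd.date_range(ts[0], ts[-1], freq=step)
    if not ts.isin(full).all():
        off = ts[~ts.isin(full)][0]
        raise ValidationError(
            f"{path}: timestamp {off} not on the {sampling_interval}-min grid"
        )
    ser = pd.Series(values, index=ts).reindex(full)
    if flags is None:
        out_flags = np.where(ser.notna(), FLAG_OBSERVED, FLAG_GAP).astype(object)
    else:
        out_flags = (
            pd.Series(flags, index=ts).reindex(full, fill_value=FLAG_GAP).to_numpy()
        )
    return HiveSeries(
        hive_id=hive_id,
        variable=variable,
        site=site,
        experiment=experiment,
        timestamps=full,
        values=ser.to_numpy(),
        sampling_interval=sampling_interval,
        flags=out_flags,
    )


def write_series(series: HiveSeries, path: str | Path) -> None:
    """Write a series as ``timestamp,value,flag`` CSV (gap values empty)."""
    df = pd.DataFrame(
        {
            "timestamp": series.timestamps.strftime("%Y-%m-%dT%H:%M:%S"),
            "value": [
                "" if f == FLAG_GAP else repr(float(v))
                for v, f in zip(series.values, series.flags)
            ],
            "flag": series.flags,
        }
    )
    df.to_csv(path, index=False)
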