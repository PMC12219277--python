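"""Shared fixtures: small synthetic series and subsets built in memory."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from hiverhythm.core import HiveSeries, SubsetWindow


def make_series(
    values: np.ndarray,
    sampling_interval: int = 30,
    variable: str = "temperature",
    start: str = "2023-12-08",
    **kw,
) -> HiveSeries:
    n = len(values)
    ts = pd.date_range(
        pd.Timestamp(start), periods=n, freq=pd.Timedelta(minutes=sampling_interval)
    )
    return HiveSeries(
        hive_id=kw.pop("hive_id", "hiveA"),
        variable=variable,
        site=kw.pop("site", "CSU"),
        experiment=kw.pop("experiment", "test"),
        timestamps=ts,
        values=values,
        sampling_interval=sampling_interval,
        **kw,
    )


def make_subset(
    values: np.ndarray, sampling_interval: int = 30, start: str = "2023-12-08", index: int = 1
) -> SubsetWindow:
    s = make_series(values, sampling_interval, start=start, detrended=True)
    return SubsetWindow(
        parent=s,
        index=index,
        timestamps=s.timestamps,
        values=s.values,
        sampling_interval=sampling_interval,
        flags=s.flags,
    )


def cosine_subset(
    amplitude: float = 1.0,
    period_h: float = 24.0,
    phase: float = 0.0,
    mesor: float = 0.0,
    hours: float = 72.0,
    sampling_interval: int = 30,
    noise_sd: float = 0.0,
    seed: int = 0,
    start: str = "2023-12-08",
) -> SubsetWindow:
    n = int(round(hours * 60.0 / sampling_interval))
    t = np.arange(n) * sampling_interval / 60.0
    y = mesor + amplitude * np.cos(2 * np.pi * t / period_h + phase)
    if noise_sd > 0:
        y = y + np.random.default_rng(seed).normal(0.0, noise_sd, n)
    return make_subset(y, sampling_interval, start=start)


@pytest.fixture
def pure_cos24():
    """Noiseless unit-amplitude 24 h cosine over 72 h at 30-min sampling."""
    return cosine_subset()
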