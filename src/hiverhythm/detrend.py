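"""Detrending by subtraction of a centered 48 h running average.

A 48 h window passes linear trends through untouched and, spanning exactly
two cycles of a 24 h oscillation, averages that oscillation to (near) zero,
so the residual keeps the daily rhythm while dropping multi-day drift.  The
window is centered — a trailing average would lag the trend and shift every
acrophase, and phase is the endpoint of this analysis — and forced to an odd
sample count so it is symmetric about its center.  Positions whose window
reaches past the data, or covers a gap, are invalid: no partial or
renormalized windows.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .core import FLAG_GAP, HiveSeries, ValidationError


def window_points(window_h: float, sampling_interval: int) -> int:
    """Odd sample count covering ``window_h`` hours: window_h*60/dt + 1."""
    n = int(round(window_h * 60.0 / sampling_interval)) + 1
    if n % 2 == 0:
        n += 1
    return n


def moving_average(series: HiveSeries, window_h: float = 48.0) -> HiveSeries:
    """Centered running mean; NaN wherever the window is incomplete.

    The returned series has the same grid as the input.  The first and last
    ``(window-1)/2`` positions, and any position whose window overlaps a gap,
    are NaN with a ``gap`` flag.
    """
    w = window_points(window_h, series.sampling_interval)
    if len(series) < w:
        raise ValidationError(
            f"series has {len(series)} points but the {window_h:g} h window needs {w}"
        )
    vals = np.where(series.flags == FLAG_GAP, np.nan, series.values)
    ma = pd.Series(vals).rolling(window=w, center=True, min_periods=w).mean().to_numpy()
    flags = np.where(np.isfinite(ma), "observed", FLAG_GAP).astype(object)
    return series.with_values(ma, flags)


def detrend(series: HiveSeries, window_h: float = 48.0) -> HiveSeries:
    """Residuals raw − centered running average, trimmed to the valid span.

    The leading and trailing ``window_h/2`` hours are removed entirely
    (their windows extend past the data); interior positions whose window
    covers a gap stay on the grid as NaN gap points.
    """
    ma = moving_average(series, window_h)
    resid = series.values - ma.values
    half = (window_points(window_h, series.sampling_interval) - 1) // 2
    sl = slice(half, len(series) - half)
    flags = np.where(np.isfinite(resid[sl]), series.flags[sl], FLAG_GAP).astype(object)
    from dataclasses import replace

    return replace(
        series,
        timestamps=series.timestamps[sl],
        values=resid[sl],
        flags=flags,
        detrended=True,
    )


def ma_attenuation(period_h: float, window_h: float, sampling_interval: int) -> float:
    """Closed-form attenuation the detrender applies to a sinusoid.

    A centered moving average of ``n`` points at spacing ``dt`` scales a
    sinusoid of angular frequency w by the Dirichlet kernel
    ``sin(n w dt / 2) / (n sin(w dt / 2))``; the residual (raw − average)
    therefore keeps ``1 −`` that factor of its amplitude.
    """
    n = window_points(window_h, sampling_interval)
    dt = sampling_interval / 60.0
    w = 2.0 * np.pi / period_h
    kernel = np.sin(n * w * dt / 2.0) / (n * np.sin(w * dt / 2.0))
    return 1.0 - kernel
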