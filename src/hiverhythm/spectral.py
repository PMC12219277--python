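"""Periodicity quantification.

Two estimators, matched to two sampling situations:

* the classical periodogram on gap-free, regularly sampled 72 h subsets,
  reported as *proportion sums of squares* — each Fourier ordinate divided by
  the total, so contributions across frequencies sum to one and the statistic
  is unit-free (equivalently, spectral density over variance times N−1);
* the Lomb-Scargle periodogram on 6-d spans, which tolerates missing points
  and an arbitrary period grid, used to estimate free-running periods
  restricted to periods below 30 h.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import lombscargle as _scipy_lombscargle

from .core import HiveSeries, SubsetWindow, ValidationError


@dataclass
class PeriodogramResult:
    """Classical periodogram of one mean-removed, regularly sampled subset.

    ``spec`` sums to the total (corrected) sum of squares (N−1)·variance;
    ``proportion_ss`` is ``spec`` normalized to sum to one.
    """

    frequencies: np.ndarray  # cycles / hour, Fourier grid j/(N dt)
    periods: np.ndarray  # hours
    spec: np.ndarray
    proportion_ss: np.ndarray
    n_points: int
    variance: float
    hive_id: str = ""
    subset_index: int = 0


@dataclass
class LombScargleResult:
    period_grid: np.ndarray  # hours
    power: np.ndarray  # normalized LS power
    peak_period: float  # hours
    hive_id: str = ""
    variable: str = ""


def classical_periodogram(subset: SubsetWindow) -> PeriodogramResult:
    """Periodogram ordinates at the Fourier frequencies of a 72 h subset.

    The scaling satisfies Parseval's identity: the ordinates sum to the
    corrected sum of squares, so ``proportion_ss`` is exactly the share of
    variance each Fourier frequency contributes.

    Raises
    ------
    ValidationError
        If the subset has gaps (use :func:`lomb_scargle` instead) or its
        values are constant (the proportion is undefined at zero variance).
    """
    if subset.has_gaps:
        raise ValidationError(
            "subset has gaps; the classical periodogram needs a regular grid — "
            "use lomb_scargle for unevenly observed spans"
        )
    x = np.asarray(subset.values, dtype=float)
    n = len(x)
    if n < 8:
        raise ValidationError(f"need >= 8 points, got {n}")
    var = float(np.var(x, ddof=1))
    if var <= 0.0 or np.ptp(x) == 0.0:
        raise ValidationError("constant subset: zero variance, proportions undefined")

    dt_h = subset.sampling_interval / 60.0
    xc = x - x.mean()
    X = np.fft.rfft(xc)
    j = np.arange(1, n // 2 + 1)
    # |X_j|^2 * 2/n for interior ordinates; the Nyquist ordinate (even n)
    # appears once and carries weight 1/n, so the total equals sum((x-xbar)^2)
    weights = np.full(len(j), 2.0 / n)
    if n % 2 == 0:
        weights[-1] = 1.0 / n
    spec = weights * np.abs(X[1 : n // 2 + 1]) ** 2
    freqs = j / (n * dt_h)
    return PeriodogramResult(
        frequencies=freqs,
        periods=1.0 / freqs,
        spec=spec,
        proportion_ss=spec / spec.sum(),
        n_points=n,
        variance=var,
        hive_id=getattr(subset, "hive_id", ""),
        subset_index=subset.index,
    )


def period_strength(
    result: PeriodogramResult, target_period_h: float, min_period_h: float = 8.0
) -> float:
    """Proportion of the sum of squares at the Fourier period nearest target.

    The target must lie on the Fourier grid to within 1e-6 relative; asking
    for an off-grid period (e.g. 48 h from a 72 h window, whose grid is
    72, 36, 24, 18, ...) is an error naming the nearest available periods.
    ``min_period_h`` bounds the reporting table, mirroring the convention of
    displaying periods >= 8 h.
    """
    idx = int(np.argmin(np.abs(result.periods - target_period_h)))
    nearest = result.periods[idx]
    if abs(nearest - target_period_h) > 1e-6 * target_period_h:
        lo = result.periods[min(idx + 1, len(result.periods) - 1)]
        raise ValidationError(
            f"{target_period_h:g} h is not a Fourier period of this window; "
            f"nearest available: {nearest:g} h and {lo:g} h"
        )
    if nearest < min_period_h:
        raise ValidationError(
            f"target {target_period_h:g} h below reporting bound {min_period_h:g} h"
        )
    return float(result.proportion_ss[idx])


def strength_table(result: PeriodogramResult, min_period_h: float = 8.0):
    """(period_h, proportion_ss) rows restricted to periods >= min_period_h."""
    keep = result.periods >= min_period_h
    return result.periods[keep], result.proportion_ss[keep]


def lomb_scargle(
    span: HiveSeries,
    min_period_h: float = 2.0,
    max_period_h: float = 30.0,
    oversample: int = 4,
) -> LombScargleResult:
    """Normalized Lomb-Scargle power over periods in (min_period_h, max_period_h).

    The frequency grid has ``oversample`` times the nominal Fourier
    resolution 1/T.  Gap points are simply dropped — uneven sampling is the
    reason to use this estimator.  The peak period is the argmax of the
    power; exact ties break toward the longer period.
    """
    good = np.isfinite(span.values)
    t = span.hours[good]
    y = span.values[good]
    if len(y) < 32:
        raise ValidationError(f"need >= 32 valid points for Lomb-Scargle, got {len(y)}")
    T = t[-1] - t[0]
    # a gap-free 72 h span has first-to-last distance 72 h minus one step
    if T < 3 * 24.0 - 1.0:
        raise ValidationError(f"span covers {T:.1f} h; >= 72 h required")
    # grid at integer multiples of the (oversampled) Fourier step, so an
    # evenly sampled input is probed at its exact Fourier frequencies
    T_grid = T + float(np.median(np.diff(t)))
    df = 1.0 / (T_grid * oversample)
    k0 = int(np.ceil(1.0 / (max_period_h * df) - 1e-9))
    k1 = int(np.floor(1.0 / (min_period_h * df) + 1e-9))
    freqs = np.arange(k0, k1 + 1) * df
    freqs = freqs[(freqs > 1.0 / max_period_h) & (freqs < 1.0 / min_period_h)]
    ang = 2.0 * np.pi * freqs
    power = _scipy_lombscargle(t, y - y.mean(), ang, normalize=True)
    periods = 1.0 / freqs
    best = np.flatnonzero(power == power.max())
    peak = float(periods[best.min()])  # lowest frequency among ties = longest period
    return LombScargleResult(
        period_grid=periods,
        power=power,
        peak_period=peak,
        hive_id=span.hive_id,
        variable=span.variable,
    )


def average_periodograms(results: list[LombScargleResult]):
    """Pointwise mean power and standard error across hives.

    Returns ``(period_grid, mean_power, se_power, mean_peak, se_peak)``.
    All results must share one period grid.
    """
    if not results:
        raise ValidationError("no periodograms to average")
    grid = results[0].period_grid
    for r in results[1:]:
        if len(r.period_grid) != len(grid) or not np.allclose(r.period_grid, grid):
            raise ValidationError("period grids differ; cannot average")
    P = np.vstack([r.power for r in results])
    n = P.shape[0]
    mean = P.mean(axis=0)
    se = P.std(axis=0, ddof=1) / np.sqrt(n) if n > 1 else np.zeros_like(mean)
    peaks = np.array([r.peak_period for r in results])
    peak_se = float(peaks.std(ddof=1) / np.sqrt(n)) if n > 1 else 0.0
    return grid, mean, se, float(peaks.mean()), peak_se
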