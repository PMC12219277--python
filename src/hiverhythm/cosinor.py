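"""Single-component cosinor rhythmometry on 3-d detrended subsets.

The model is ``y(t) = M + A·cos(2πt/τ + φ) + e`` fitted by ordinary least
squares on the linearized regressors cos(2πt/τ) and sin(2πt/τ):

    y = M + β·cos(ωt) + γ·sin(ωt),   A = sqrt(β² + γ²),  φ = atan2(−γ, β)

with t in hours from local midnight of the subset's first calendar day, so
acrophases pooled across subsets and hives share one angular reference.
The acrophase is corrected into (−2π, 0]; the peak occurs ``−φ·τ/2π`` hours
after midnight.  Rhythm detection uses the zero-amplitude F test comparing
the cosinor fit against the intercept-only model.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .core import SubsetWindow, ValidationError

TWO_PI = 2.0 * np.pi


@dataclass
class CosinorFit:
    mesor: float
    amplitude: float
    acrophase: float  # radians in (-2*pi, 0]
    period_h: float
    r_squared: float
    f_stat: float
    p_value: float
    n_points: int
    beta: float
    gamma: float
    rss: float
    rss0: float
    hive_id: str = ""
    subset_index: int = 0
    degenerate: bool = False

    @property
    def peak_clock_h(self) -> float:
        """Clock time of the fitted peak, hours after local midnight, in [0, 24)."""
        return float((-self.acrophase * self.period_h / TWO_PI) % 24.0)

    def predict(self, t_hours: np.ndarray) -> np.ndarray:
        return self.mesor + self.amplitude * np.cos(
            TWO_PI * np.asarray(t_hours) / self.period_h + self.acrophase
        )


def correct_acrophase(raw_phase: float, beta: float, gamma: float) -> float:
    """Map the quadrant-correct phase atan2(−γ, β) into (−2π, 0].

    With the convention ``A·cos(ωt + φ)``, β = A·cosφ and γ = −A·sinφ, so
    atan2(−γ, β) recovers φ in (−π, π]; subtracting 2π from positive values
    yields the conventional corrected acrophase in (−2π, 0].
    """
    if beta == 0.0 and gamma == 0.0:
        raise ValidationError("zero amplitude: acrophase undefined")
    phi = float(np.arctan2(-gamma, beta))
    if phi > 0.0:
        phi -= TWO_PI
    return phi


def fit_cosinor(subset: SubsetWindow, period_h: float = 24.0) -> CosinorFit:
    """Least-squares cosinor fit at a fixed trial period.

    Gap points are dropped.  Requires at least 8 valid points spanning a full
    period.  A flat subset returns a degenerate zero-amplitude fit rather
    than an error, so batch runs survive dead sensors.
    """
    good = np.isfinite(subset.values)
    t = subset.hours_since_midnight[good]
    y = np.asarray(subset.values, dtype=float)[good]
    n = len(y)
    if n < 8:
        raise ValidationError(f"need >= 8 valid points, got {n}")
    if t[-1] - t[0] < period_h:
        raise ValidationError(
            f"span {t[-1] - t[0]:.1f} h shorter than one {period_h:g} h period"
        )
    w = TWO_PI / period_h
    X = np.column_stack([np.ones(n), np.cos(w * t), np.sin(w * t)])
    coef, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    mesor, beta, gamma = (float(c) for c in coef)
    resid = y - X @ coef
    rss = float(resid @ resid)
    rss0 = float(np.sum((y - y.mean()) ** 2))

    amplitude = float(np.hypot(beta, gamma))
    degenerate = amplitude < 1e-12 * max(1.0, abs(mesor))
    if degenerate:
        acro = 0.0
        amplitude = 0.0
    else:
        acro = correct_acrophase(np.arctan2(-gamma, beta), beta, gamma)
    r2 = 0.0 if rss0 == 0.0 else 1.0 - rss / rss0
    f, p = _zero_amplitude(rss0, rss, n)
    return CosinorFit(
        mesor=mesor,
        amplitude=amplitude,
        acrophase=acro,
        period_h=period_h,
        r_squared=r2,
        f_stat=f,
        p_value=p,
        n_points=n,
        beta=beta,
        gamma=gamma,
        rss=rss,
        rss0=rss0,
        hive_id=getattr(subset, "hive_id", ""),
        subset_index=subset.index,
        degenerate=degenerate,
    )


def _zero_amplitude(rss0: float, rss: float, n: int) -> tuple[float, float]:
    if n <= 3:
        raise ValidationError("zero-amplitude test needs n > 3")
    if rss <= 0.0:
        return float("inf"), 0.0
    f = ((rss0 - rss) / 2.0) / (rss / (n - 3))
    p = float(stats.f.sf(f, 2, n - 3))
    return float(f), p


def zero_amplitude_test(fit: CosinorFit) -> tuple[float, float]:
    """F test of the rhythm against the intercept-only model.

    ``F = ((RSS0 − RSS)/2) / (RSS/(n−3))`` with (2, n−3) degrees of freedom,
    where RSS0 is the residual sum of squares of the mean-only fit.
    """
    return _zero_amplitude(fit.rss0, fit.rss, fit.n_points)


def estimate_period(
    subset: SubsetWindow,
    tau_min_h: float = 16.0,
    tau_max_h: float = 32.0,
    tau_step_h: float = 0.05,
) -> tuple[float, CosinorFit]:
    """Best-fit period ("daylength") by R² grid search over trial periods.

    Refits the cosinor at every τ on the grid and returns the τ maximizing
    R² (ties to the smaller τ) together with the winning fit.  The grid must
    stay between a third of the span and the span itself so each trial
    period completes at least one cycle.
    """
    good = np.isfinite(subset.values)
    span = (
        subset.hours_since_midnight[good][-1] - subset.hours_since_midnight[good][0]
        if good.any()
        else 0.0
    )
    grid = np.arange(tau_min_h, tau_max_h + 0.5 * tau_step_h, tau_step_h)
    grid = grid[(grid > span / 3.0) & (grid < span)]
    if len(grid) == 0:
        raise ValidationError(
            f"empty period grid within (span/3, span) = ({span / 3.0:.1f}, {span:.1f}) h"
        )
    best_fit = None
    best_r2 = -np.inf
    for tau in grid:
        fit = fit_cosinor(subset, period_h=float(tau))
        if fit.r_squared > best_r2 + 1e-15:
            best_r2 = fit.r_squared
            best_fit = fit
    assert best_fit is not None
    return best_fit.period_h, best_fit
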