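"""Circular statistics for pooled acrophases.

Acrophases live on the circle, so ordinary means and t-tests do not apply.
This module provides the von Mises maximum-likelihood fit (the circular
analogue of the normal), Watson's U² goodness-of-fit and two-sample
homogeneity tests, the circular median with its median deviation, hourly
rose-diagram binning, and conversion between radians and clock time.

P-values for the two-sample test are reported as table ranges
(">0.1" ... "<0.001"), the format circular-statistics software prints, with
an optional seeded permutation (two-sample) or parametric bootstrap
(goodness of fit) exact p as a verifiable companion.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .core import ValidationError

TWO_PI = 2.0 * np.pi

#: asymptotic critical values for the two-sample Watson U²
U2_CRITICAL = ((0.385, "<0.001"), (0.268, "<0.01"), (0.187, "<0.05"), (0.152, "<0.1"))

P_RANGES = (">0.1", "<0.1", "<0.05", "<0.01", "<0.001")


@dataclass
class PhaseSample:
    """A pooled collection of phase angles with provenance.

    Angles are radians wrapped into [0, 2π); each entry is one
    (hive x 3-d subset) acrophase.
    """

    angles: np.ndarray
    interval: str = ""
    site: str = ""
    variable: str = ""
    sources: list = field(default_factory=list)

    def __post_init__(self) -> None:
        a = np.asarray(self.angles, dtype=float)
        if a.size == 0:
            raise ValidationError("PhaseSample needs at least one angle")
        if not np.all(np.isfinite(a)):
            raise ValidationError("angles must be finite")
        self.angles = np.mod(a, TWO_PI)

    @property
    def n(self) -> int:
        return len(self.angles)


@dataclass
class CircTestResult:
    statistic: float
    p_range: str
    p_exact: float | None
    n1: int
    n2: int = 0
    test: str = ""


# ---------------------------------------------------------------------------
# von Mises fitting


def _mean_direction(angles: np.ndarray) -> tuple[float, float]:
    C = float(np.cos(angles).sum())
    S = float(np.sin(angles).sum())
    Rbar = np.hypot(C, S) / len(angles)
    return float(np.arctan2(S, C)) % TWO_PI, Rbar


def _kappa_from_rbar(rbar) -> np.ndarray:
    """Standard piecewise inverse of the mean resultant length."""
    r = np.asarray(rbar, dtype=float)
    k = np.empty_like(r)
    lo = r < 0.53
    mid = (r >= 0.53) & (r < 0.85)
    hi = r >= 0.85
    k[lo] = 2.0 * r[lo] + r[lo] ** 3 + 5.0 * r[lo] ** 5 / 6.0
    k[mid] = -0.4 + 1.39 * r[mid] + 0.43 / (1.0 - r[mid])
    with np.errstate(divide="ignore"):
        k[hi] = 1.0 / (r[hi] ** 3 - 4.0 * r[hi] ** 2 + 3.0 * r[hi])
    return k


KAPPA_CAP = 1e6


def vonmises_mle(sample: PhaseSample) -> tuple[float, float]:
    """Maximum-likelihood (μ, κ) of a von Mises fit.

    μ is the mean direction atan2(Σsin, Σcos); κ inverts the mean resultant
    length R̄ by the usual three-branch approximation.  A degenerate sample
    (all angles equal) returns κ capped at 1e6; R̄ = 0 returns κ = 0 with
    μ = nan (undefined direction).
    """
    if sample.n < 2:
        raise ValidationError("von Mises fit needs n >= 2")
    mu, rbar = _mean_direction(sample.angles)
    if rbar < 1e-12:
        return float("nan"), 0.0
    kappa = float(_kappa_from_rbar(rbar))
    if not np.isfinite(kappa) or kappa > KAPPA_CAP:
        kappa = KAPPA_CAP
    return mu, kappa


# ---------------------------------------------------------------------------
# Watson U² statistics


def _u2_one_sample(u: np.ndarray) -> float:
    """Watson U² from probability-integral-transformed values in [0, 1]."""
    u = np.sort(u)
    n = len(u)
    i = np.arange(1, n + 1)
    ubar = u.mean()
    return float(np.sum((u - (2 * i - 1) / (2 * n)) ** 2) - n * (ubar - 0.5) ** 2 + 1.0 / (12 * n))


def _pit_vonmises(angles: np.ndarray, mu: float, kappa: float) -> np.ndarray:
    centered = np.mod(angles - mu + np.pi, TWO_PI) - np.pi  # wrap to (-pi, pi]
    return stats.vonmises.cdf(centered, kappa)


def _p_to_range(p: float) -> str:
    for bound, label in ((0.001, "<0.001"), (0.01, "<0.01"), (0.05, "<0.05"), (0.1, "<0.1")):
        if p < bound:
            return label
    return ">0.1"


def watson_gof_vonmises(
    sample: PhaseSample, n_boot: int = 1000, seed: int | None = None
) -> CircTestResult:
    """Watson U² goodness of fit to the fitted von Mises distribution.

    U² is computed from the probability integral transform under the MLE
    (μ̂, κ̂).  Because both parameters are estimated, the null distribution is
    approximated by a parametric bootstrap that refits each replicate; the
    reported p_range is the bin the bootstrap p falls in.  Small samples
    (n < 17) are legal but the test is weak there.
    """
    n = sample.n
    if n < 4:
        raise ValidationError("Watson goodness of fit needs n >= 4")
    mu, kappa = vonmises_mle(sample)
    if not np.isfinite(mu):
        raise ValidationError("mean direction undefined (R̄ = 0)")
    u2 = _u2_one_sample(_pit_vonmises(sample.angles, mu, kappa))

    rng = np.random.default_rng(seed)
    # vectorized bootstrap: each row one replicate, refit (mu, kappa) per row
    theta = rng.vonmises(mu, kappa, size=(n_boot, n))
    C = np.cos(theta).sum(axis=1)
    S = np.sin(theta).sum(axis=1)
    mu_b = np.arctan2(S, C)
    rbar_b = np.hypot(C, S) / n
    kap_b = np.minimum(_kappa_from_rbar(rbar_b), KAPPA_CAP)
    centered = np.mod(theta - mu_b[:, None] + np.pi, TWO_PI) - np.pi
    u = np.sort(stats.vonmises.cdf(centered, kap_b[:, None]), axis=1)
    i = np.arange(1, n + 1)
    u2_b = (
        np.sum((u - (2 * i - 1) / (2 * n)) ** 2, axis=1)
        - n * (u.mean(axis=1) - 0.5) ** 2
        + 1.0 / (12 * n)
    )
    p = float((np.sum(u2_b >= u2) + 1) / (n_boot + 1))
    return CircTestResult(
        statistic=u2, p_range=_p_to_range(p), p_exact=p, n1=n, test="watson_gof_vonmises"
    )


def _u2_two_sample(a: np.ndarray, b: np.ndarray) -> float:
    n1, n2 = len(a), len(b)
    N = n1 + n2
    pooled = np.concatenate([a, b])
    labels = np.concatenate([np.zeros(n1), np.ones(n2)])
    order = np.argsort(pooled, kind="stable")
    lab = labels[order]
    cdf1 = np.cumsum(lab == 0) / n1
    cdf2 = np.cumsum(lab == 1) / n2
    d = cdf1 - cdf2
    return float(n1 * n2 / N**2 * (np.sum(d**2) - np.sum(d) ** 2 / N))


def watson_two_sample(
    a: PhaseSample, b: PhaseSample, n_perm: int = 0, seed: int | None = None
) -> CircTestResult:
    """Watson's two-sample U² test of homogeneity on the circle.

    The statistic is computed from the pooled empirical CDFs and compared
    against the asymptotic critical values 0.152 / 0.187 / 0.268 / 0.385 for
    p = 0.1 / 0.05 / 0.01 / 0.001.  Combined samples below 17 are allowed
    but the asymptotic table is unreliable there — prefer ``n_perm > 0``,
    which adds an exact permutation p by label shuffling.  U² is invariant
    under a common rotation of both samples.
    """
    if a.n == 0 or b.n == 0:
        raise ValidationError("both samples must be nonempty")
    u2 = _u2_two_sample(a.angles, b.angles)
    p_range = ">0.1"
    for crit, label in U2_CRITICAL:
        if u2 > crit:
            p_range = label
            break
    p_exact = None
    if n_perm > 0:
        rng = np.random.default_rng(seed)
        pooled = np.concatenate([a.angles, b.angles])
        count = 0
        for _ in range(n_perm):
            perm = rng.permutation(pooled)
            if _u2_two_sample(perm[: a.n], perm[a.n :]) >= u2:
                count += 1
        p_exact = float((count + 1) / (n_perm + 1))
    return CircTestResult(
        statistic=u2, p_range=p_range, p_exact=p_exact, n1=a.n, n2=b.n, test="watson_two_sample"
    )


# ---------------------------------------------------------------------------
# location, spread, binning, conversion


def circular_distance(x, y) -> np.ndarray:
    """Shorter arc length between angles, in [0, π]."""
    d = np.abs(np.mod(np.asarray(x) - np.asarray(y), TWO_PI))
    return np.where(d > np.pi, TWO_PI - d, d)


def circular_median_mad(sample: PhaseSample) -> tuple[float, float]:
    """Circular median and median deviation.

    The median is the sample angle minimizing the mean circular absolute
    deviation; ties break first toward the smaller circular MAD (median of
    circular distances to the candidate), then toward the smaller angle.
    The returned deviation is the median circular distance to the median.
    """
    a = np.sort(sample.angles)
    if len(a) == 1:
        return float(a[0]), 0.0
    dist = circular_distance(a[:, None], a[None, :])
    mean_dev = dist.mean(axis=1)
    mad = np.median(dist, axis=1)
    # lexicographic: mean deviation, then MAD, then angle (a is sorted)
    best = np.lexsort((a, mad, np.round(mean_dev, 12)))[0]
    return float(a[best]), float(mad[best])


def rose_bins(sample: PhaseSample, n_bins: int = 24) -> np.ndarray:
    """Counts over half-open angular bins [k·2π/n, (k+1)·2π/n).

    With the default 24 bins each bin is one clock hour of a 24 h cycle;
    boundary angles go to the higher bin.
    """
    if n_bins < 2:
        raise ValidationError("need at least 2 bins")
    idx = np.floor(sample.angles * n_bins / TWO_PI).astype(int) % n_bins
    return np.bincount(idx, minlength=n_bins)


def rad_to_clock(delta: float, period_h: float = 24.0) -> tuple[int, int]:
    """Express a nonnegative angular difference as (hours, whole minutes).

    Decimal hours are ``delta·period/2π``; minutes are truncated, not
    rounded.  Negative input is an error — map differences into [0, 2π)
    first (phase changes are conventionally reported as positive).
    """
    if delta < 0:
        raise ValidationError("negative angle: normalize into [0, 2*pi) first")
    dec_h = delta * period_h / TWO_PI
    dec_h = round(dec_h, 9)  # shield floor() from float dust
    hours = int(np.floor(dec_h))
    minutes = int(np.floor(round((dec_h - hours) * 60.0, 6)))
    return hours, minutes


def clock_to_rad(hours: float, period_h: float = 24.0) -> float:
    return hours * TWO_PI / period_h


def phase_contrast(a: PhaseSample, b: PhaseSample) -> float:
    """Circular difference of mean directions (a − b), reported in [0, 2π)."""
    mu_a, r_a = _mean_direction(a.angles)
    mu_b, r_b = _mean_direction(b.angles)
    if r_a < 1e-12 or r_b < 1e-12:
        raise ValidationError("mean direction undefined (R̄ = 0)")
    return float(np.mod(mu_a - mu_b, TWO_PI))
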