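"""Classical periodogram and Lomb-Scargle: Parseval, oracles, invariances."""

import numpy as np
import pytest

from hiverhythm import (
    ValidationError,
    average_periodograms,
    classical_periodogram,
    lomb_scargle,
    period_strength,
)

from conftest import cosine_subset, make_series, make_subset


def brute_force_periodogram(x, dt_h):
    """O(N^2) DFT oracle with the variance-sum scaling."""
    x = np.asarray(x, float)
    n = len(x)
    xc = x - x.mean()
    spec = []
    for j in range(1, n // 2 + 1):
        c = np.sum(xc * np.cos(2 * np.pi * j * np.arange(n) / n))
        s = np.sum(xc * np.sin(2 * np.pi * j * np.arange(n) / n))
        w = 1.0 / n if (n % 2 == 0 and j == n // 2) else 2.0 / n
        spec.append(w * (c * c + s * s))
    return np.array(spec)


class TestClassicalPeriodogram:
    def test_pure_24h_cosine_puts_all_mass_at_24h(self, pure_cos24):
        pg = classical_periodogram(pure_cos24)
        i24 = np.argmin(np.abs(pg.periods - 24.0))
        assert pg.proportion_ss[i24] == pytest.approx(1.0, abs=1e-12)
        others = np.delete(pg.proportion_ss, i24)
        assert np.abs(others).max() < 1e-12

    def test_proportions_sum_to_one_for_noise(self):
        sub = make_subset(np.random.default_rng(0).normal(size=144))
        pg = classical_periodogram(sub)
        assert pg.proportion_ss.sum() == pytest.approx(1.0, abs=1e-9)

    def test_parseval_spec_sum_equals_corrected_ss(self):
        sub = make_subset(np.random.default_rng(1).normal(size=144))
        pg = classical_periodogram(sub)
        assert pg.spec.sum() == pytest.approx((pg.n_points - 1) * pg.variance, rel=1e-12)

    def test_constant_subset_raises(self):
        with pytest.raises(ValidationError, match="variance"):
            classical_periodogram(make_subset(np.full(144, 3.0)))

    def test_gappy_subset_directed_to_lomb_scargle(self):
        vals = np.random.default_rng(2).normal(size=144)
        vals[7] = np.nan
        with pytest.raises(ValidationError, match="omb"):
            classical_periodogram(make_subset(vals))

    @pytest.mark.parametrize("n", [96, 144, 145, 512])
    def test_matches_brute_force_dft(self, n):
        vals = np.random.default_rng(n).normal(size=n)
        pg = classical_periodogram(make_subset(vals))
        oracle = brute_force_periodogram(vals, 0.5)
        np.testing.assert_allclose(pg.spec, oracle, rtol=1e-9, atol=1e-12)

    def test_scale_invariance(self):
        vals = np.random.default_rng(3).normal(size=144)
        a = classical_periodogram(make_subset(vals))
        b = classical_periodogram(make_subset(37.5 * vals))
        np.testing.assert_allclose(a.proportion_ss, b.proportion_ss, rtol=1e-12)

    def test_circular_shift_invariance_for_periodic_input(self):
        t = np.arange(144) * 0.5
        y = np.cos(2 * np.pi * t / 24.0) + 0.5 * np.cos(2 * np.pi * t / 12.0 + 1.0)
        a = classical_periodogram(make_subset(y))
        b = classical_periodogram(make_subset(np.roll(y, 17)))
        np.testing.assert_allclose(a.proportion_ss, b.proportion_ss, atol=1e-9)


class TestPeriodStrength:
    def test_24h_cosine_strength_is_one(self, pure_cos24):
        pg = classical_periodogram(pure_cos24)
        assert period_strength(pg, 24.0) == pytest.approx(1.0, abs=1e-12)

    def test_orthogonal_frequency_strength_is_zero(self, pure_cos24):
        pg = classical_periodogram(pure_cos24)
        assert period_strength(pg, 36.0) == pytest.approx(0.0, abs=1e-12)

    def test_off_grid_period_raises_naming_neighbours(self, pure_cos24):
        pg = classical_periodogram(pure_cos24)
        with pytest.raises(ValidationError, match="not a Fourier period"):
            period_strength(pg, 48.0)


class TestLombScargle:
    def test_recovers_noncircadian_period(self):
        # noiseless 25.4 h cosine, 6 d at 5-min sampling
        n = 6 * 24 * 12
        t = np.arange(n) / 12.0
        s = make_series(np.cos(2 * np.pi * t / 25.4 + 0.4), 5)
        r = lomb_scargle(s, oversample=4)
        grid_step = 25.4**2 / (6 * 24.0 * 4)  # dP = P^2 * df at the peak
        assert abs(r.peak_period - 25.4) <= grid_step

    def test_matches_classical_maxima_on_even_grid(self):
        rng = np.random.default_rng(4)
        t = np.arange(144) * 0.5
        y = np.cos(2 * np.pi * t / 24.0) + 0.3 * rng.normal(size=144)
        s = make_series(y, 30)
        ls = lomb_scargle(s, oversample=1, min_period_h=4.0)
        pg = classical_periodogram(make_subset(y))
        ls_peak = ls.peak_period
        pg_peak = pg.periods[np.argmax(pg.spec)]
        assert abs(ls_peak - pg_peak) < 1.0

    def test_tolerates_missing_points(self):
        n = 6 * 24 * 12
        t = np.arange(n) / 12.0
        y = np.cos(2 * np.pi * t / 25.4)
        y[100:400] = np.nan  # 25 h hole
        s = make_series(y, 5)
        r = lomb_scargle(s, oversample=4)
        assert abs(r.peak_period - 25.4) < 0.7

    def test_pure_noise_peak_is_weak(self):
        n = 6 * 24 * 12
        rng = np.random.default_rng(5)
        noise = make_series(rng.normal(size=n), 5)
        t = np.arange(n) / 12.0
        signal = make_series(np.cos(2 * np.pi * t / 25.4), 5)
        assert lomb_scargle(noise).power.max() < 0.2 * lomb_scargle(signal).power.max()

    def test_too_few_points_raises(self):
        vals = np.full(4 * 24 * 12, np.nan)
        vals[:20] = 1.0
        with pytest.raises(ValidationError, match="32"):
            lomb_scargle(make_series(vals, 5))


class TestAveragePeriodograms:
    def test_identical_inputs_have_zero_se(self):
        n = 6 * 24 * 12
        t = np.arange(n) / 12.0
        s = make_series(np.cos(2 * np.pi * t / 24.0), 5)
        results = [lomb_scargle(s) for _ in range(8)]
        _, _, se, mean_peak, se_peak = average_periodograms(results)
        assert se.max() < 1e-12
        assert se_peak == 0.0

    def test_mean_and_se_of_two_peaks(self):
        n = 6 * 24 * 12
        t = np.arange(n) / 12.0
        r1 = lomb_scargle(make_series(np.cos(2 * np.pi * t / 25.0), 5), oversample=8)
        r2 = lomb_scargle(make_series(np.cos(2 * np.pi * t / 27.0), 5), oversample=8)
        _, _, _, mean_peak, se_peak = average_periodograms([r1, r2])
        assert mean_peak == pytest.approx(26.0, abs=0.3)
        assert se_peak == pytest.approx(1.0, abs=0.3)

    def test_mismatched_grids_raise(self):
        n = 6 * 24 * 12
        t = np.arange(n) / 12.0
        r1 = lomb_scargle(make_series(np.cos(2 * np.pi * t / 25.0), 5), oversample=4)
        r2 = lomb_scargle(make_series(np.cos(2 * np.pi * t / 25.0), 5), oversample=8)
        with pytest.raises(ValidationError, match="grid"):
            average_periodograms([r1, r2])

    def test_simulated_hives_recover_mean_peak(self):
        rng = np.random.default_rng(6)
        n = 6 * 24 * 12
        t = np.arange(n) / 12.0
        results = []
        for _ in range(8):
            y = np.cos(2 * np.pi * t / 25.4 + rng.uniform(0, 2 * np.pi))
            y += 0.2 * rng.normal(size=n)
            results.append(lomb_scargle(make_series(y, 5), oversample=8))
        _, _, _, mean_peak, se_peak = average_periodograms(results)
        assert abs(mean_peak - 25.4) <= max(2 * se_peak, 0.3)
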