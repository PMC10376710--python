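import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from statsmodels.tsa.stattools import acf as sm_acf

from spacetrend import spectral
from spacetrend.spectral import (
    AutocorrelationProfile,
    autocorrelation_profile,
    autocorrelations,
    build_null,
    classify_series,
    lomb_scargle_power,
    significance_adjust,
    spectral_grids,
)


def lstsq_power(values, times, freqs):
    """Independent oracle: half the explained sum of squares of a
    per-frequency least-squares sinusoid fit to the centered series."""
    x = values - values.mean()
    out = []
    for f in freqs:
        design = np.column_stack(
            [np.cos(2 * np.pi * f * times), np.sin(2 * np.pi * f * times)]
        )
        beta, *_ = np.linalg.lstsq(design, x, rcond=None)
        resid = x - design @ beta
        out.append(0.5 * (np.sum(x**2) - np.sum(resid**2)))
    return np.array(out)


class TestPeriodogram:
    def test_matches_least_squares_fit_even_grid(self, rng, sgrids):
        for _ in range(5):
            x = rng.normal(size=8)
            p = lomb_scargle_power(x, sgrids.times, sgrids.freqs)
            np.testing.assert_allclose(
                p, lstsq_power(x, sgrids.times, sgrids.freqs), atol=1e-8
            )

    def test_matches_least_squares_fit_with_gaps(self, rng, sgrids):
        x = rng.normal(size=8)
        x[[2, 5]] = np.nan
        present = ~np.isnan(x)
        p = lomb_scargle_power(x, sgrids.times, sgrids.freqs)
        np.testing.assert_allclose(
            p, lstsq_power(x[present], sgrids.times[present], sgrids.freqs),
            atol=1e-8,
        )

    def test_cosine_peaks_at_its_frequency(self, sgrids):
        f0 = sgrids.freqs[2]
        x = np.cos(2 * np.pi * f0 * sgrids.times)
        p = lomb_scargle_power(x, sgrids.times, sgrids.freqs)
        assert np.argmax(p) == 2

    @settings(max_examples=40, deadline=None)
    @given(st.lists(st.floats(-50, 50), min_size=8, max_size=8))
    def test_power_nonnegative(self, values):
        sg = spectral_grids()
        x = np.array(values)
        if np.ptp(x) == 0:
            return
        p = lomb_scargle_power(x, sg.times, sg.freqs)
        assert p.min() >= -1e-12

    def test_too_few_points_rejected(self, sgrids):
        x = np.full(8, np.nan)
        x[[0, 3]] = 1.0
        with pytest.raises(ValueError, match="3 present"):
            lomb_scargle_power(x, sgrids.times, sgrids.freqs)


class TestAutocorrelations:
    def test_matches_direct_lagged_products(self, rng, sgrids):
        """On the complete grid, the inverse-FT autocorrelations equal the
        direct (biased, mean-removed) sample autocorrelation exactly."""
        for _ in range(5):
            x = rng.normal(size=8)
            rho = autocorrelation_profile(x, sgrids).rho
            direct = sm_acf(x, nlags=sgrids.n_lags, fft=False, adjusted=False)
            np.testing.assert_allclose(rho, direct, atol=1e-6)

    def test_rho0_is_one_and_bounded(self, rng, sgrids):
        for _ in range(10):
            x = rng.normal(size=8)
            x[rng.integers(0, 8)] = np.nan  # one missing bin
            rho = autocorrelation_profile(x, sgrids).rho
            assert rho[0] == pytest.approx(1.0, abs=1e-9)
            assert np.all(np.abs(rho) <= 1 + 1e-9)

    def test_long_white_noise_has_small_autocorrelation(self, rng):
        n = 128
        times = np.arange(n, dtype=float)
        freqs = np.arange(1, n + 1) / (2 * n)
        lag_times = np.arange(n // 2 + 1, dtype=float)
        x = rng.normal(size=n)
        p = lomb_scargle_power(x, times, freqs)
        rho = autocorrelations(p, freqs, lag_times)
        assert np.max(np.abs(rho[1:])) <= 3 / np.sqrt(n)

    def test_zero_power_rejected(self, sgrids):
        with pytest.raises(ValueError, match="zero"):
            autocorrelations(np.zeros(8), sgrids.freqs, sgrids.lag_times)


class TestNull:
    def test_determinism_and_quantile_monotonicity(self, rng, sgrids):
        pool = rng.normal(size=500)
        a = build_null(pool, sgrids, n_boot=2000, seed=7)
        b = build_null(pool, sgrids, n_boot=2000, seed=7)
        np.testing.assert_array_equal(a.rho_q, b.rho_q)
        assert a.max_q == b.max_q and a.min_q == b.min_q
        median = build_null(pool, sgrids, n_boot=2000, level=0.5, seed=7)
        assert np.all(a.rho_q >= median.rho_q)

    def test_empty_pool_rejected(self, sgrids):
        with pytest.raises(ValueError, match="empty"):
            build_null(np.array([]), sgrids, n_boot=10, seed=0)

    def test_held_out_calibration_quick(self, rng, sgrids):
        """~5% of fresh null series exceed the lag-1 threshold."""
        pool = rng.normal(size=2000)
        null = build_null(pool, sgrids, n_boot=20000, seed=3)
        _, rho = spectral.bootstrap_autocorrelations(
            pool, sgrids, 5000, np.random.default_rng(99)
        )
        frac_below = np.mean(rho[:, 1] < null.rho_q[0])
        assert frac_below == pytest.approx(0.95, abs=0.02)


@pytest.fixture(scope="module")
def null(sgrids):
    return build_null(
        np.random.default_rng(0).normal(scale=0.3, size=1000),
        sgrids, n_boot=5000, seed=1,
    )


class TestClassification:
    def _profile(self, rho_lags, sgrids):
        return AutocorrelationProfile(
            lags=np.arange(sgrids.n_lags + 1),
            rho=np.array([1.0, *rho_lags]),
        )

    def test_smallest_significant_lag_wins(self, null, sgrids):
        rho = null.rho_q + 0.01   # exceeds thresholds at every lag
        cls = classify_series(self._profile(rho, sgrids), np.zeros(8), null)
        assert cls.kind == spectral.LAG and cls.lag == 1
        assert cls.p_value < 1 - null.level

    def test_threshold_equality_counts(self, null, sgrids):
        rho = null.rho_q - 0.05
        rho[1] = null.rho_q[1]    # exact tie at lag 2 -> LagM with M=2
        cls = classify_series(self._profile(rho, sgrids), np.zeros(8), null)
        assert cls.kind == spectral.LAG and cls.lag == 2

    def test_no_trend_inside_all_bounds(self, null, sgrids):
        rho = null.rho_q - 0.05
        values = np.full(8, 0.5 * null.max_q)
        cls = classify_series(self._profile(rho, sgrids), values, null)
        assert cls.kind == spectral.NO_TREND and cls.lag is None
        assert cls.p_value >= 1 - null.level

    def test_spikes_require_lag_failure(self, null, sgrids):
        below = null.rho_q - 0.05
        spike = np.zeros(8)
        spike[5] = null.max_q + 1.0
        cls = classify_series(self._profile(below, sgrids), spike, null)
        assert cls.kind == spectral.SPIKE_MAX
        dip = np.zeros(8)
        dip[5] = null.min_q - 1.0
        cls = classify_series(self._profile(below, sgrids), dip, null)
        assert cls.kind == spectral.SPIKE_MIN
        # the same extremum with a significant lag is a Lag class instead
        cls = classify_series(self._profile(null.rho_q + 0.01, sgrids), spike, null)
        assert cls.kind == spectral.LAG

    def test_planted_archetypes_recovered(self, lag_cohort, spike_cohort):
        for cohort, min_sens in ((lag_cohort, 0.9), (spike_cohort, 0.9)):
            _, truth, prep = cohort
            table, _ = spectral.classify_cohort(prep.normalized, n_boot=4000, seed=3)
            idx = table.set_index(["subject_id", "measurement_id"])
            keys = [k for k in truth.planted if k in idx.index]
            hits = np.mean([idx.loc[k, "kind"] == truth.planted[k] for k in keys])
            assert hits >= min_sens

    def test_classify_cohort_deterministic(self, lag_cohort):
        _, _, prep = lag_cohort
        sub = prep.normalized.loc[["S01", "S02"]]
        t1, _ = spectral.classify_cohort(sub, n_boot=1000, seed=5)
        t2, _ = spectral.classify_cohort(sub, n_boot=1000, seed=5)
        pd.testing.assert_frame_equal(t1, t2)


class TestFDR:
    def test_bh_worked_example(self):
        sel = significance_adjust(np.array([0.001, 0.02, 0.8]), alpha=0.05)
        assert sel.tolist() == [True, True, False]

    def test_all_ones_select_nothing(self):
        assert not significance_adjust(np.ones(5)).any()

    def test_appending_large_p_never_removes(self, rng):
        p = rng.uniform(size=20) ** 3
        base = significance_adjust(p)
        extended = significance_adjust(np.append(p, 0.9))
        assert np.all(extended[:20] >= base)

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            significance_adjust(np.array([0.5, 1.5]))
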