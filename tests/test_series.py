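"""Proxy-series conditioning: transforms, binning, compositing, detrending."""

import numpy as np
import pytest

import pyroclim as pc
from pyroclim.errors import (DegenerateInputError, InvalidInputError,
                             InvalidParameterError)


class TestTransformFire:
    def test_log1p_fixes_zero(self, series_factory):
        out = pc.transform_fire(series_factory([0, 0, 0]), "log1p")
        np.testing.assert_array_equal(out.value, [0, 0, 0])

    def test_log1p_value(self, series_factory):
        out = pc.transform_fire(series_factory([3.0]), "log1p")
        np.testing.assert_allclose(out.value, [1.3862944], atol=1e-7)

    def test_sqrt(self, series_factory):
        out = pc.transform_fire(series_factory([4.0]), "sqrt")
        np.testing.assert_array_equal(out.value, [2.0])

    def test_negative_input_rejected(self, series_factory):
        with pytest.raises(InvalidInputError):
            pc.transform_fire(series_factory([1.0, -0.5]), "log1p")

    def test_unknown_method_rejected(self, series_factory):
        with pytest.raises(InvalidParameterError):
            pc.transform_fire(series_factory([1.0]), "cube")


class TestStandardize:
    def test_hand_computed_example(self, series_factory):
        out = pc.standardize(series_factory([1, 2, 3]))
        np.testing.assert_allclose(out.value, [-1, 0, 1], atol=1e-12)

    def test_idempotent(self, series_factory, rng):
        s = series_factory(rng.normal(5, 3, 100))
        once = pc.standardize(s)
        twice = pc.standardize(once)
        np.testing.assert_allclose(once.value, twice.value, atol=1e-10)

    def test_affine_invariant(self, series_factory, rng):
        x = rng.normal(0, 1, 50)
        a = pc.standardize(series_factory(x))
        b = pc.standardize(series_factory(3.7 * x - 11.0))
        np.testing.assert_allclose(a.value, b.value, atol=1e-10)

    def test_constant_series_rejected(self, series_factory):
        with pytest.raises(DegenerateInputError):
            pc.standardize(series_factory([2.0] * 10))


class TestBinSeries:
    def test_constant_series(self, series_factory):
        s = series_factory(np.ones(400))
        out = pc.bin_series(s, 200, "mean")
        np.testing.assert_array_equal(out.value, [1.0, 1.0])
        np.testing.assert_array_equal(out.time, [0.0, 200.0])

    def test_mean_of_index_values(self, series_factory):
        out = pc.bin_series(series_factory(np.arange(10.0)), 5, "mean")
        np.testing.assert_array_equal(out.value, [2.0, 7.0])

    def test_sum_counts(self, series_factory):
        out = pc.bin_series(series_factory(np.ones(10)), 5, "sum")
        np.testing.assert_array_equal(out.value, [5.0, 5.0])

    def test_sum_conserves_total(self, series_factory, rng):
        vals = rng.exponential(1.0, 100)
        out = pc.bin_series(series_factory(vals), 7, "sum")
        assert np.nansum(out.value) == pytest.approx(vals.sum())

    def test_empty_bins_are_missing(self):
        s = pc.ProxySeries(time=np.array([0.0, 1.0, 10.0]),
                           value=np.array([1.0, 1.0, 1.0]))
        out = pc.bin_series(s, 3, "mean")
        assert np.isnan(out.value[1])

    def test_nonpositive_width_rejected(self, series_factory):
        with pytest.raises(InvalidParameterError):
            pc.bin_series(series_factory([1, 2]), 0)


class TestComposite:
    def test_single_site_identity(self, series_factory, rng):
        s = series_factory(rng.normal(0, 1, 100))
        comp = pc.composite([s], 10)
        ref = pc.bin_series(pc.standardize(s), 10, "mean")
        np.testing.assert_allclose(comp.value, ref.value, atol=1e-12)
        assert (comp.n_sites_per_bin == 1).all()

    def test_duplicated_site_changes_nothing(self, series_factory, rng):
        s = series_factory(rng.normal(0, 1, 100))
        one = pc.composite([s], 10)
        two = pc.composite([s, s], 10)
        np.testing.assert_allclose(one.value, two.value, atol=1e-12)
        assert (two.n_sites_per_bin == 2).all()

    def test_affine_sites_recover_common_signal(self, series_factory, rng):
        signal = rng.normal(0, 1, 200)
        a = series_factory(signal)
        b = series_factory(5.0 * signal + 2.0)
        comp = pc.composite([a, b], 20)
        ref = pc.bin_series(pc.standardize(a), 20, "mean")
        np.testing.assert_allclose(comp.value, ref.value, atol=1e-10)

    def test_site_order_irrelevant(self, series_factory, rng):
        sites = [series_factory(rng.normal(0, 1, 80)) for _ in range(4)]
        fwd = pc.composite(sites, 10)
        rev = pc.composite(sites[::-1], 10)
        np.testing.assert_allclose(fwd.value, rev.value, atol=1e-12)

    def test_partial_coverage_counts_sites(self, series_factory, rng):
        a = series_factory(rng.normal(0, 1, 100), start=0)
        b = series_factory(rng.normal(0, 1, 100), start=50)
        comp = pc.composite([a, b], 50)
        assert comp.n_sites_per_bin.tolist() == [1, 2, 1]


class TestDetrend:
    def test_pure_line_maps_to_zero(self, series_factory):
        s = series_factory(2.5 * np.arange(20.0) - 4.0)
        np.testing.assert_allclose(pc.detrend_linear(s).value, 0.0, atol=1e-10)

    def test_recovers_orthogonalized_residuals(self, rng):
        t = np.arange(50.0)
        resid = rng.normal(0, 1, 50)
        # orthogonalize the residuals against [1, t] so they survive OLS exactly
        basis = np.vstack([np.ones(50), t]).T
        resid -= basis @ np.linalg.lstsq(basis, resid, rcond=None)[0]
        s = pc.ProxySeries(time=t, value=3.0 * t + 1.0 + resid)
        np.testing.assert_allclose(pc.detrend_linear(s).value, resid, atol=1e-8)

    def test_idempotent(self, series_factory, rng):
        s = series_factory(rng.normal(0, 1, 60) + 0.1 * np.arange(60))
        once = pc.detrend_linear(s)
        np.testing.assert_allclose(pc.detrend_linear(once).value, once.value,
                                   atol=1e-10)

    def test_residuals_orthogonal_to_time(self, series_factory, rng):
        out = pc.detrend_linear(series_factory(rng.normal(0, 5, 100)))
        assert abs(out.value.mean()) < 1e-8
        assert abs(np.cov(out.value, out.time)[0, 1]) < 1e-8

    def test_short_series_rejected(self, series_factory):
        with pytest.raises(DegenerateInputError):
            pc.detrend_linear(series_factory([1.0, 2.0]))


class TestMovingCumulative:
    def test_constant_rate(self, series_factory):
        out = pc.moving_cumulative(series_factory(np.ones(200)), 100, 10)
        np.testing.assert_array_equal(out.value, 100.0)
        assert out.resolution == 10

    def test_window_count(self, series_factory):
        out = pc.moving_cumulative(series_factory(np.ones(150)), 100, 10)
        assert len(out) == 6  # floor((150-100)/10) + 1

    def test_spike_mass_appears_in_covering_windows(self, series_factory):
        vals = np.zeros(150)
        vals[125] = 42.0
        out = pc.moving_cumulative(series_factory(vals), 100, 10)
        # windows starting at 30..50 cover year 125 given window=100
        expected = np.where((out.time <= 125) & (out.time + 100 > 125), 42.0, 0.0)
        np.testing.assert_array_equal(out.value, expected)

    def test_oversized_window_rejected(self, series_factory):
        with pytest.raises(InvalidParameterError):
            pc.moving_cumulative(series_factory(np.ones(50)), 100)


class TestCharcoalPrepare:
    def test_lambda_one_matches_plain_composite(self, series_factory, rng):
        sites = [series_factory(rng.exponential(2.0, 400)) for _ in range(3)]
        cfg = pc.CharcoalConfig(bin_width=200, boxcox_lambda=1.0)
        prepared = pc.charcoal_prepare(sites, cfg)
        plain = pc.composite(sites, 200)
        np.testing.assert_allclose(prepared.value, plain.value, atol=1e-10)

    def test_constant_site_rejected(self, series_factory):
        with pytest.raises(DegenerateInputError):
            pc.charcoal_prepare([series_factory([3.0] * 400)])

    def test_log_transform_scale_invariance(self, series_factory, rng):
        # at lambda=0 (log), a site scaled by any factor composites identically
        shape = rng.exponential(1.0, 400) + 0.5
        a = series_factory(shape)
        b = series_factory(250.0 * shape)
        cfg = pc.CharcoalConfig(bin_width=200, boxcox_lambda=0.0, shift_frac=1e-9)
        one = pc.charcoal_prepare([a], cfg)
        two = pc.charcoal_prepare([a, b], cfg)
        np.testing.assert_allclose(one.value, two.value, atol=1e-6)
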