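"""Sliding windows, windowed measures and piecewise-linear trend fits."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import vforg as v


class TestSlidingWindows:
    @pytest.mark.parametrize(
        "n, L, H, expected",
        [
            (210_000, 1000, 500, 420),  # the full-record window count
            (1000, 1000, 500, 2),
            (500, 1000, 500, 1),
            (1500, 1000, 500, 3),
        ],
    )
    def test_window_counts(self, n, L, H, expected):
        assert len(v.sliding_windows(n, L, H)) == expected

    def test_rejects_invalid_hop(self):
        with pytest.raises(v.ParameterError):
            v.sliding_windows(1000, 100, 0)
        with pytest.raises(v.ParameterError):
            v.sliding_windows(1000, 100, 200)

    @given(
        n=st.integers(min_value=1, max_value=5000),
        L=st.integers(min_value=1, max_value=1200),
        H=st.integers(min_value=1, max_value=1200),
    )
    def test_count_matches_closed_form(self, n, L, H):
        if H > L or n < H:
            return
        windows = v.sliding_windows(n, L, H)
        # retained windows start at multiples of H and keep length >= H
        assert len(windows) == (n - H) // H + 1
        for i, (start, end) in enumerate(windows):
            assert start == i * H
            assert end == min(start + L, n)
            assert end - start >= H

    def test_windows_ordered_and_cover_record(self):
        windows = v.sliding_windows(4321, 1000, 500)
        starts = [s for s, _ in windows]
        assert starts == sorted(starts)
        assert windows[-1][1] <= 4321


class TestWindowedMeasure:
    def test_synchronized_ensemble_stays_near_one(self):
        layout = v.generate_layout(8, seed=0)
        ens, _ = v.generate_clustered_ensemble(
            layout, 1, [7.0], 1.0, 0.0, 0.01, 0.0, 4.0, 1000.0, seed=1
        )
        series = v.windowed_measure(
            ens, v.LagSpec(d=50), v.organization_measure, 1000, 500
        )
        assert np.all(series.values > 0.95)

    def test_sync_to_noise_switch_is_visible(self):
        layout = v.generate_layout(8, seed=0)
        sync, _ = v.generate_clustered_ensemble(
            layout, 1, [7.0], 1.0, 0.0, 0.05, 0.0, 4.0, 1000.0, seed=2
        )
        noise = v.generate_noise_ensemble(8, 4.0, 1000.0, 1.0, seed=3)
        ens = v.SignalEnsemble(
            data=np.hstack([sync.data, noise.data]), fs=1000.0
        )
        series = v.windowed_measure(
            ens, v.LagSpec(d=50), v.organization_measure, 1000, 500
        )
        half = len(series) // 2
        assert series.values[: half - 1].mean() > series.values[half + 1 :].mean()

    def test_deterministic_across_runs(self):
        layout = v.generate_layout(6, seed=4)
        ens, _ = v.generate_clustered_ensemble(
            layout, 2, [5.0, 9.0], 0.9, 0.0, 0.1, 0.0, 4.0, 1000.0, seed=5
        )
        a = v.windowed_measure(ens, v.LagSpec(d=40), v.organization_measure)
        b = v.windowed_measure(ens, v.LagSpec(d=40), v.organization_measure)
        np.testing.assert_array_equal(a.values, b.values)

    def test_windows_too_short_for_lag_search_are_skipped(self):
        layout = v.generate_layout(4, seed=6)
        ens, _ = v.generate_clustered_ensemble(
            layout, 1, [7.0], 0.9, 0.0, 0.1, 0.0, 3.5, 1000.0, seed=7
        )
        # final truncated 500-sample window cannot host d = 400
        series = v.windowed_measure(
            ens, v.LagSpec(d=400), v.organization_measure, 1000, 500
        )
        assert len(series) == len(v.sliding_windows(3500, 1000, 500)) - 1
        assert np.all(series.ends - series.starts >= 802)


class TestPiecewiseLinearFit:
    def test_exact_line_has_zero_slope_changes(self):
        t = np.linspace(0, 10, 101)
        fit = v.piecewise_linear_fit(t, 2.0 * t + 1.0, knots=[3.0, 7.0])
        assert fit.intercept == pytest.approx(1.0, abs=1e-10)
        assert fit.slope == pytest.approx(2.0, abs=1e-10)
        np.testing.assert_allclose(fit.slope_changes, 0.0, atol=1e-10)

    def test_noiseless_spline_parameters_recovered(self):
        t = np.linspace(0, 12, 200)
        true = v.TrendFit(
            intercept=0.7, slope=0.1, slope_changes=np.array([-0.3, 0.5]),
            knots_s=np.array([4.0, 8.0]), times_s=t, fitted=np.zeros_like(t),
        )
        fit = v.piecewise_linear_fit(t, true.predict(t), knots=[4.0, 8.0])
        assert fit.intercept == pytest.approx(0.7, abs=1e-8)
        assert fit.slope == pytest.approx(0.1, abs=1e-8)
        np.testing.assert_allclose(fit.slope_changes, [-0.3, 0.5], atol=1e-8)

    def test_constant_series(self):
        t = np.linspace(0, 5, 60)
        fit = v.piecewise_linear_fit(t, np.full_like(t, 3.3), knots=[2.0])
        assert fit.slope == pytest.approx(0.0, abs=1e-10)
        np.testing.assert_allclose(fit.slope_changes, 0.0, atol=1e-10)

    def test_residuals_orthogonal_to_spline_basis(self):
        rng = np.random.default_rng(0)
        t = np.linspace(0, 10, 150)
        y = 0.5 - 0.02 * t + rng.normal(scale=0.1, size=t.size)
        fit = v.piecewise_linear_fit(t, y, knots=[3.0, 6.0])
        X = v.trends.spline_design(t, np.array([3.0, 6.0]))
        np.testing.assert_allclose(X.T @ (y - fit.fitted), 0.0, atol=1e-8)

    def test_segment_slopes_accumulate_changes(self):
        t = np.linspace(0, 9, 120)
        y = v.TrendFit(
            intercept=0.0, slope=1.0, slope_changes=np.array([-0.5, 0.25]),
            knots_s=np.array([3.0, 6.0]), times_s=t, fitted=np.zeros_like(t),
        ).predict(t)
        fit = v.piecewise_linear_fit(t, y, knots=[3.0, 6.0])
        np.testing.assert_allclose(fit.segment_slopes(), [1.0, 0.5, 0.75], atol=1e-8)

    def test_rank_deficient_design_rejected(self):
        with pytest.raises(v.ParameterError):
            v.piecewise_linear_fit([0.0, 1.0, 2.0], [1.0, 2.0, 3.0], knots=[5.0, 6.0])

    def test_unsorted_knots_rejected(self):
        t = np.linspace(0, 10, 50)
        with pytest.raises(v.ParameterError):
            v.piecewise_linear_fit(t, t, knots=[7.0, 3.0])


class TestEpochSummary:
    def make_fit(self, intercept, slope, changes):
        t = np.linspace(0, 10, 40)
        return v.TrendFit(
            intercept=intercept, slope=slope, slope_changes=np.asarray(changes),
            knots_s=np.array([3.0, 6.0]), times_s=t, fitted=np.zeros_like(t),
        )

    def test_single_recording_reports_zero_sd_with_flag(self):
        frame = v.epoch_summary([self.make_fit(0.6, -0.1, [0.05, -0.02])])
        assert frame.attrs["single_recording"]
        np.testing.assert_array_equal(frame["sd"], 0.0)

    def test_two_identical_fits_have_zero_sd(self):
        fit = self.make_fit(0.6, -0.1, [0.05, -0.02])
        frame = v.epoch_summary([fit, self.make_fit(0.6, -0.1, [0.05, -0.02])])
        assert frame.loc[0, "mean"] == pytest.approx(0.6)
        np.testing.assert_allclose(frame["sd"], 0.0, atol=1e-15)

    def test_three_fits_match_direct_arithmetic(self):
        fits = [
            self.make_fit(0.5, -0.1, [0.0, 0.1]),
            self.make_fit(0.7, -0.2, [0.3, -0.1]),
            self.make_fit(0.6, -0.3, [0.3, 0.3]),
        ]
        frame = v.epoch_summary(fits).set_index("parameter")
        assert frame.loc["intercept", "mean"] == pytest.approx(0.6)
        assert frame.loc["intercept", "sd"] == pytest.approx(0.1)
        assert frame.loc["slope", "mean"] == pytest.approx(-0.2)
        assert frame.loc["slope_change_at_3s", "mean"] == pytest.approx(0.2)
        assert frame.loc["slope_change_at_3s", "sd"] == pytest.approx(
            np.std([0.0, 0.3, 0.3], ddof=1)
        )

    def test_mismatched_knots_rejected(self):
        a = self.make_fit(0.5, 0.0, [0.0, 0.0])
        b = v.TrendFit(
            intercept=0.5, slope=0.0, slope_changes=np.array([0.0]),
            knots_s=np.array([4.0]), times_s=np.zeros(3), fitted=np.zeros(3),
        )
        with pytest.raises(v.ParameterError):
            v.epoch_summary([a, b])
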