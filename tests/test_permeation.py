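import numpy as np
import pytest

from ivpt import (
    FitError,
    PermeationProfile,
    ReceptorSeries,
    ValidationError,
    cumulative_permeation,
    dense_channel_count,
    dense_flux,
    diffusion_coefficient,
    fit_steady_state,
    permeability_coefficient,
    required_array_area,
    steady_state_css,
    summarize_group,
)
from ivpt.simulate import SimulationTruth, fickian_cumulative, simulate_franz

from conftest import series_from_profile


class TestCumulativePermeation:
    def test_all_zero_concentrations_give_zero_profile(self, cell_config):
        series = ReceptorSeries("r1", [0.0, 1.0, 2.0], [0.0, 0.0, 0.0])
        profile = cumulative_permeation(series, cell_config)
        np.testing.assert_array_equal(profile.q, 0.0)

    def test_single_sample_no_correction_term(self, cell_config):
        series = ReceptorSeries("r1", [1.0], [1.0])
        profile = cumulative_permeation(series, cell_config)
        assert profile.q[0] == pytest.approx(5.0 * 1.0 / 0.64)  # 7.8125

    def test_withdrawal_correction_accumulates(self, cell_config):
        # second point must credit the 0.3 mL aliquot removed at the first
        series = ReceptorSeries("r1", [1.0, 2.0], [1.0, 2.0])
        profile = cumulative_permeation(series, cell_config)
        np.testing.assert_allclose(profile.q, [7.8125, (5.0 * 2 + 0.3 * 1) / 0.64])
        assert profile.q[1] == pytest.approx(16.09375)


class TestFitSteadyState:
    def test_exact_line_recovered(self):
        t = np.array([2.0, 4.0, 6.0, 8.0])
        profile = PermeationProfile(t, 2.0 * (t - 1.0))
        fit = fit_steady_state(profile)
        assert fit.slope == pytest.approx(2.0)
        assert fit.lag_time == pytest.approx(1.0)
        assert fit.r_squared == pytest.approx(1.0)
        assert not fit.lag_is_negative

    def test_burn_in_excluded_on_fickian_curve(self):
        # slow membrane: D = 2e-5 sq·cm/h, h = 0.031 cm -> lag = h²/6D ≈ 8 h;
        # steady state needs ~2 lag times, so sample densely out to 48 h
        truth = SimulationTruth(d=2e-5, partition=0.4, h=0.031, c=1000.0)
        t = np.arange(0.0, 49.0)
        profile = PermeationProfile(t, fickian_cumulative(t, truth))
        fit = fit_steady_state(profile)
        assert fit.segment_start_index > 0  # early curvature excluded
        assert fit.lag_time == pytest.approx(truth.lag_time, rel=0.10)
        assert fit.slope == pytest.approx(truth.steady_flux, rel=0.02)

    def test_flat_positive_profile_is_nonpositive_flux(self):
        profile = PermeationProfile([1.0, 2.0, 3.0], [5.0, 5.0, 5.0])
        with pytest.raises(FitError, match="non-positive flux"):
            fit_steady_state(profile)

    def test_no_linear_segment_reports_best_r2(self):
        t = np.arange(8.0)
        q = np.array([0.0, 5.0, 1.0, 6.0, 2.0, 7.0, 3.0, 8.0])
        with pytest.raises(FitError, match="no linear segment"):
            fit_steady_state(profile=PermeationProfile(t, q), r2_threshold=0.999)

    def test_negative_lag_flagged_and_clamped(self):
        t = np.array([1.0, 2.0, 3.0, 4.0])
        profile = PermeationProfile(t, 2.0 * t + 1.0)  # positive intercept
        fit = fit_steady_state(profile)
        assert fit.lag_is_negative
        assert fit.lag_time == 0.0
        assert fit.lag_time_raw == pytest.approx(-0.5)

    def test_too_few_points_rejected(self):
        with pytest.raises(FitError, match="at least 3"):
            fit_steady_state(PermeationProfile([1.0, 2.0], [1.0, 2.0]))


class TestTransportParameters:
    @pytest.mark.parametrize(
        "j,expected",
        [(0.34, 3.40e-4), (1.69, 16.90e-4), (0.0, 0.0)],
    )
    def test_permeability_coefficient(self, j, expected):
        assert permeability_coefficient(j, 1000.0) == pytest.approx(expected)

    def test_permeability_needs_positive_concentration(self):
        with pytest.raises(ValidationError):
            permeability_coefficient(1.0, 0.0)

    def test_diffusion_coefficient_lag_relation(self):
        assert diffusion_coefficient(0.06, 6.0) == pytest.approx(1.0e-4)
        # group-mean lag times of the two microneedle arms
        assert diffusion_coefficient(0.031, 4.16) == pytest.approx(3.850e-5, rel=1e-3)
        assert diffusion_coefficient(0.031, 1.33) == pytest.approx(1.204e-4, rel=1e-3)

    def test_diffusion_requires_positive_lag(self):
        with pytest.raises(ValidationError, match="lag time"):
            diffusion_coefficient(0.031, 0.0)

    @pytest.mark.parametrize(
        "area,expected",
        [(9267.40, 10791), (8567.11, 11673), (1e8, 1)],
    )
    def test_dense_channel_count(self, area, expected):
        assert dense_channel_count(area) == expected

    def test_dense_channel_count_rounds_half_up(self):
        assert dense_channel_count(1e8 / 10.5) == 11

    @pytest.mark.parametrize(
        "j,n_dense,n_actual,expected",
        [(1.69, 10791, 100, 182.37), (0.34, 11673, 69, 57.52)],
    )
    def test_dense_flux_matches_channel_scaling(self, j, n_dense, n_actual, expected):
        assert dense_flux(j, n_dense, n_actual) == pytest.approx(expected, abs=0.005)

    def test_dense_flux_identity_when_counts_equal(self):
        assert dense_flux(1.69, 500, 500) == 1.69

    def test_css_from_dense_flux(self):
        css = steady_state_css(0.64, 182.37, 118.0)
        assert css == pytest.approx(988.92, rel=0.005)
        assert steady_state_css(0.64, 57.52, 118.0) == pytest.approx(311.58, rel=0.005)
        assert steady_state_css(0.64, 0.0, 118.0) == 0.0

    def test_required_array_area_inverts_css(self):
        area = required_array_area(337.0, 118.0, 182.37)
        assert area == pytest.approx(337.0 * 118.0 / (1000.0 * 182.37))
        assert area == pytest.approx(0.218, abs=0.001)
        assert required_array_area(0.0, 118.0, 182.37) == 0.0

    def test_linearity_and_inverse_scaling(self):
        # Kp and Css scale linearly with flux; required area inversely
        assert permeability_coefficient(2.0, 1000.0) == 2 * permeability_coefficient(1.0, 1000.0)
        assert steady_state_css(0.64, 3.0, 118.0) == pytest.approx(
            3 * steady_state_css(0.64, 1.0, 118.0), rel=1e-12
        )
        assert required_array_area(337.0, 118.0, 2.0) == pytest.approx(
            required_array_area(337.0, 118.0, 1.0) / 2.0
        )


class TestSummarizeGroup:
    def _series_with_lag(self, lag, cfg, slope=2.0, rep="r"):
        t = np.array([lag + 1, lag + 2, lag + 4, lag + 6, lag + 8])
        return series_from_profile(t, slope * (t - lag), cfg, replicate_id=rep)

    def test_per_replicate_then_average_is_default(self, cell_config):
        reps = [
            self._series_with_lag(4.0, cell_config, rep="a"),
            self._series_with_lag(5.0, cell_config, rep="b"),
        ]
        summary = summarize_group("g", reps, cell_config)
        h = cell_config.skin_thickness
        d_per_rep = np.mean([h**2 / (6 * 4.0), h**2 / (6 * 5.0)])
        assert summary.mean["d"] == pytest.approx(d_per_rep, rel=1e-6)
        # averaging lag first gives a *different* (Jensen) value
        d_aggregate = h**2 / (6 * 4.5)
        assert summary.mean["d"] != pytest.approx(d_aggregate, rel=1e-4)

    def test_aggregate_order_transforms_once(self, cell_config):
        reps = [
            self._series_with_lag(4.0, cell_config, rep="a"),
            self._series_with_lag(5.0, cell_config, rep="b"),
        ]
        summary = summarize_group("g", reps, cell_config, order="aggregate")
        h = cell_config.skin_thickness
        assert summary.mean["d"] == pytest.approx(h**2 / (6 * 4.5), rel=1e-6)

    def test_single_replicate_sd_zero_with_n_flag(self, cell_config):
        summary = summarize_group(
            "g", [self._series_with_lag(2.0, cell_config)], cell_config
        )
        assert summary.n == 1
        assert all(sd == 0.0 for sd in summary.sd.values())

    def test_identical_replicates_have_zero_sd(self, cell_config):
        reps = [
            self._series_with_lag(3.0, cell_config, rep="a"),
            self._series_with_lag(3.0, cell_config, rep="b"),
        ]
        summary = summarize_group("g", reps, cell_config)
        assert summary.sd["flux"] == pytest.approx(0.0, abs=1e-12)
        assert summary.sd["d"] == pytest.approx(0.0, abs=1e-12)

    def test_dense_factor_scales_css_only(self, cell_config):
        reps = [self._series_with_lag(2.0, cell_config)]
        plain = summarize_group("g", reps, cell_config)
        dense = summarize_group("g", reps, cell_config, dense_factor=10.0)
        assert dense.mean["css"] == pytest.approx(10 * plain.mean["css"])
        assert dense.mean["flux"] == plain.mean["flux"]
        assert dense.mean["kp"] == plain.mean["kp"]

    def test_empty_group_rejected(self, cell_config):
        with pytest.raises(ValidationError):
            summarize_group("g", [], cell_config)
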