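"""Thermal summation fits and degree-hour accumulation."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

import thermodev as td
from thermodev.datasets import load_thermal_reference, stage_mean_points


def hyperbola_points(K, D0, temps):
    return [(K / (T - D0), T) for T in temps]


class TestAccumulatedDegreeHours:
    def test_threshold_equality_gives_zero(self):
        log = td.generate_temperature_log(td.ConstantProfile(20.0), 100)
        assert td.accumulated_degree_hours(log, 20.0, 0, 100) == 0.0

    def test_constant_temperature_closed_form(self):
        log = td.generate_temperature_log(td.ConstantProfile(25.0), 150)
        adh = td.accumulated_degree_hours(log, 11.81, 0, 100)
        assert adh == pytest.approx((25 - 11.81) * 100, rel=1e-12)

    def test_sinusoid_matches_fine_quadrature(self):
        """Hourly trapezoid vs 1-minute quadrature, threshold inside the
        sinusoid's range so clamping is active."""
        log = td.generate_temperature_log(td.SinusoidProfile(15, 5, 24), 24)
        adh = td.accumulated_degree_hours(log, 14.0, 0, 24)
        t = np.arange(0, 24 + 1e-9, 1 / 60)
        fine = np.trapezoid(np.clip(15 + 5 * np.sin(2 * np.pi * t / 24) - 14,
                                    0, None), t)
        assert adh == pytest.approx(fine, rel=0.005)

    def test_additive_over_abutting_intervals(self):
        log = td.generate_temperature_log(td.SinusoidProfile(20, 5, 24), 72)
        a = td.accumulated_degree_hours(log, 12.0, 0, 30.5)
        b = td.accumulated_degree_hours(log, 12.0, 30.5, 72)
        c = td.accumulated_degree_hours(log, 12.0, 0, 72)
        assert a + b == pytest.approx(c, abs=1e-9)

    def test_monotone_in_threshold(self):
        log = td.generate_temperature_log(td.SinusoidProfile(20, 5, 24), 48)
        vals = [td.accumulated_degree_hours(log, d0, 0, 48)
                for d0 in (5, 10, 15, 18)]
        assert all(x >= y for x, y in zip(vals, vals[1:]))

    def test_interval_outside_span_rejected(self):
        log = td.generate_temperature_log(td.ConstantProfile(20.0), 48)
        with pytest.raises(td.CoverageError):
            td.accumulated_degree_hours(log, 10.0, -5, 20)


class TestExactRecovery:
    @pytest.mark.parametrize("fit", [td.fit_thermal_ikemoto,
                                     td.fit_thermal_rate])
    def test_noiseless_hyperbola_recovered(self, fit):
        res = fit(hyperbola_points(300.0, 10.0, (15, 20, 25)))
        assert res.K == pytest.approx(300.0, rel=1e-9)
        assert res.D0 == pytest.approx(10.0, rel=1e-9)

    @given(st.floats(50, 5000), st.floats(-5, 12),
           st.integers(3, 6))
    def test_recovery_for_random_parameters(self, K, D0, n_temps):
        temps = np.linspace(max(D0 + 2.0, 13.0), max(D0 + 2.0, 13.0) + 12,
                            n_temps)
        pts = hyperbola_points(K, D0, temps)
        for fit in (td.fit_thermal_ikemoto, td.fit_thermal_rate):
            res = fit(pts)
            assert res.K == pytest.approx(K, rel=1e-9)
            assert res.D0 == pytest.approx(D0, rel=1e-9, abs=1e-9)

    def test_methods_agree_on_noiseless_and_differ_on_noisy(self):
        pts = hyperbola_points(600.0, 8.0, (14, 18, 22, 26))
        ik = td.fit_thermal_ikemoto(pts)
        rt = td.fit_thermal_rate(pts)
        assert ik.K == pytest.approx(rt.K, rel=1e-9)
        rng = np.random.default_rng(0)
        noisy = [(d * np.exp(rng.normal(0, 0.1)), T) for d, T in pts]
        ikn = td.fit_thermal_ikemoto(noisy)
        rtn = td.fit_thermal_rate(noisy)
        assert abs(ikn.K - 600) / 600 < 0.10 and abs(rtn.K - 600) / 600 < 0.10
        assert ikn.K != pytest.approx(rtn.K, rel=1e-6)


class TestPublishedAnchors:
    """Means-based refits land inside the tolerance band around the
    published stage parameters (replicate-level raw data are unpublished,
    so exact reproduction is impossible by construction)."""

    @pytest.mark.parametrize("stage", ["hatching", "instar3", "total"])
    def test_well_fitting_stages_within_band(self, stage):
        ref = load_thermal_reference().set_index("stage").loc[stage]
        res = td.fit_thermal_ikemoto(stage_mean_points(stage), stage=stage)
        assert abs(res.D0 - ref["D0"]) <= 1.0
        assert abs(res.K - ref["K"]) / ref["K"] <= 0.15

    def test_total_duration_threshold_value(self):
        res = td.fit_thermal_ikemoto(stage_mean_points("total"))
        assert res.D0 == pytest.approx(5.51, abs=0.01)


class TestFitErrors:
    def test_identical_durations_singular(self):
        with pytest.raises(td.FitError):
            td.fit_thermal_ikemoto([(30.0, 15), (30.0, 20), (30.0, 25)])

    def test_negative_rate_slope_rejected(self):
        # durations increasing with temperature: inverted thermal response
        with pytest.raises(td.FitError):
            td.fit_thermal_rate([(10.0, 15), (20.0, 20), (40.0, 25)])

    def test_fewer_than_three_points_rejected(self):
        with pytest.raises(td.FitError):
            td.fit_thermal_ikemoto([(30.0, 15), (20.0, 25)])


class TestExcludeNonlinearPoints:
    def collinear_with_outlier(self):
        temps = [14, 16, 18, 20, 22, 24]
        pts = hyperbola_points(400.0, 9.0, temps)
        d, t = pts[3]
        pts[3] = (d * 10, t)  # gross displacement
        return pts, (d * 10, t)

    def test_gross_outlier_excluded(self):
        pts, outlier = self.collinear_with_outlier()
        kept, excluded = td.exclude_nonlinear_points(pts, 3.0)
        assert len(excluded) == 1
        assert excluded[0][:2] == outlier[:2]
        assert len(kept) == len(pts) - 1

    def test_infinite_threshold_keeps_everything(self):
        pts, _ = self.collinear_with_outlier()
        kept, excluded = td.exclude_nonlinear_points(pts, float("inf"),
                                                     manual_mask=[1])
        assert len(excluded) == 1 and excluded[0][2] == "manual"
        assert len(kept) == len(pts) - 1

    def test_manual_mask_always_excluded(self):
        pts = hyperbola_points(400.0, 9.0, [14, 16, 18, 20, 22])
        kept, excluded = td.exclude_nonlinear_points(pts, 3.0, manual_mask=[0, 4])
        reasons = {e[2] for e in excluded}
        assert reasons == {"manual"}
        assert len(kept) == 3

    def test_never_reduces_below_three_points(self):
        rng = np.random.default_rng(1)
        pts = [(d + rng.normal(0, 5), T)
               for d, T in hyperbola_points(400.0, 9.0, [14, 17, 20, 23])]
        kept, _ = td.exclude_nonlinear_points(pts, 0.01)
        assert len(kept) >= 3

    def test_false_positive_rate_on_clean_data(self):
        """With threshold 3, well-behaved noisy data loses at most ~2% of
        its points (Monte-Carlo over seeds)."""
        n_points, n_excluded, n_total = 20, 0, 0
        temps = np.linspace(14, 26, n_points)
        for seed in range(300):
            rng = np.random.default_rng(seed)
            x = 400.0 / (temps - 9.0)
            y_noise = rng.normal(0, 1.0, n_points)
            pts = [(xi, Ti) for xi, Ti in zip(x, temps)]
            # perturb durations slightly (relative noise)
            pts = [(d * (1 + 0.02 * e), T) for (d, T), e in zip(pts, y_noise)]
            _, excluded = td.exclude_nonlinear_points(pts, 3.0)
            n_excluded += len(excluded)
            n_total += n_points
        assert n_excluded / n_total <= 0.02

    def test_automatic_exclusion_needs_four_points(self):
        pts = hyperbola_points(400.0, 9.0, [15, 20, 25])
        with pytest.raises(td.FitError):
            td.exclude_nonlinear_points(pts, 3.0)


class TestResultsObject:
    def test_predicted_duration_roundtrip(self):
        res = td.fit_thermal_ikemoto(hyperbola_points(300.0, 10.0, (15, 20, 25)))
        assert res.predicted_duration(20.0) == pytest.approx(30.0, rel=1e-9)
        with pytest.raises(td.CoverageError):
            res.predicted_duration(9.0)

    def test_summary_mentions_parameters(self):
        res = td.fit_thermal_ikemoto(stage_mean_points("hatching"),
                                     stage="hatching")
        text = res.summary()
        assert "K" in text and "D0" in text and "hatching" in text
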