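"""PMI engine: degree-hour inversion, evidence routes, combination."""

import numpy as np
import pytest

import thermodev as td


def thermal_params(stage="hatching", K=1319.0, D0=11.81, se_K=42.0,
                   se_D0=0.78, r2=0.97):
    return td.ThermalSummationResults(
        stage=stage, K=K, D0=D0, se_K=se_K, se_D0=se_D0, r_squared=r2,
        method="ikemoto", n_points=9)


class TestAdhRoute:
    def test_constant_temperature_closed_form(self):
        log = td.generate_temperature_log(td.ConstantProfile(25.0), 200)
        est = td.estimate_age_adh(thermal_params(), log, 150.0)
        assert est.point == pytest.approx(1319.0 / (25 - 11.81), abs=1e-6)
        assert est.interval[0] <= est.point <= est.interval[1]

    def test_short_record_reports_shortfall(self):
        log = td.generate_temperature_log(td.ConstantProfile(25.0), 50)
        with pytest.raises(td.CoverageError, match="shortfall"):
            td.estimate_age_adh(thermal_params(), log, 50.0)

    def test_near_threshold_temperature_exhausts_record(self):
        log = td.generate_temperature_log(td.ConstantProfile(11.9), 500,)
        with pytest.raises((td.CoverageError, td.ValidationError)):
            td.estimate_age_adh(thermal_params(), log, 500.0,
                                allow_extrapolation=True)

    def test_sinusoid_matches_fine_grid_accumulation(self):
        """Backward hourly solve vs brute-force 1-minute accumulation."""
        log = td.generate_temperature_log(td.SinusoidProfile(20, 5, 24), 400)
        est = td.estimate_age_adh(thermal_params(), log, 350.0)
        t = np.arange(0, 350 + 1e-9, 1 / 60)
        excess = np.clip(20 + 5 * np.sin(2 * np.pi * t / 24) - 11.81, 0, None)
        # integrate backward from discovery until K reached
        rev = np.cumsum(((excess[1:] + excess[:-1]) / 2 * np.diff(t))[::-1])
        age_fine = t[-1] - t[::-1][1:][np.searchsorted(rev, 1319.0)]
        assert est.point == pytest.approx(350.0 - (350.0 - age_fine), abs=0.1)
        assert abs(est.point - age_fine) <= 0.1

    def test_backward_solve_inverts_forward_accumulation(self):
        log = td.generate_temperature_log(td.SinusoidProfile(18, 6, 24), 600)
        t0 = td.solve_start_time(log, 10.0, 2000.0, 500.0)
        t_end = td.solve_completion_time(log, 10.0, 2000.0, t0)
        assert t_end == pytest.approx(500.0, abs=0.1)

    def test_poor_fit_carries_warning(self):
        log = td.generate_temperature_log(td.ConstantProfile(25.0), 300)
        est = td.estimate_age_adh(thermal_params(K=3086.5, D0=3.59, r2=0.21),
                                  log, 250.0)
        assert any("R2" in w for w in est.warnings)

    def test_stage_mismatch_rejected(self):
        log = td.generate_temperature_log(td.ConstantProfile(25.0), 200)
        with pytest.raises(td.ValidationError):
            td.estimate_age_adh(thermal_params(stage="hatching"), log, 150.0,
                                stage="pupation")


class TestLengthRoute:
    def test_age_adds_hatching_offset(self, noiseless_growth_models,
                                      published_isomorphen):
        m = noiseless_growth_models[20.0]
        t_star = 0.5 * m.feeding_phase_end
        L = m.predict(t_star)
        est = td.estimate_age_from_length(L, 20.0, noiseless_growth_models,
                                          published_isomorphen)
        assert est.point == pytest.approx(t_star + 43.00, abs=1e-3)

    def test_unattainable_length_rejected(self, noiseless_growth_models,
                                          published_isomorphen):
        with pytest.raises(td.ValidationError):
            td.estimate_age_from_length(40.0, 20.0, noiseless_growth_models,
                                        published_isomorphen)

    def test_out_of_range_temperature_refused_then_warned(
            self, noiseless_growth_models, published_isomorphen):
        with pytest.raises(td.ValidationError, match="validated"):
            td.estimate_age_from_length(8.0, 30.0, noiseless_growth_models,
                                        published_isomorphen)

    def test_interval_widens_near_plateau(self, truth, published_isomorphen):
        models = {20.0: td.fit_cubic_growth(
            td.generate_length_series(truth, 20.0, 12.0, seed=3), 20.0)}
        m = models[20.0]
        early = td.estimate_age_from_length(m.predict(0.45 * m.feeding_phase_end),
                                            20.0, models, published_isomorphen)
        late = td.estimate_age_from_length(
            m.predict(0.98 * m.feeding_phase_end), 20.0, models,
            published_isomorphen)
        width = lambda e: e.interval[1] - e.interval[0]
        assert width(late) > width(early)


class TestPupalRoute:
    def make_model(self, truth, temp):
        s = td.generate_pupal_series(truth, temp, 24.0, seed=0)
        return td.fit_pupal_indicator(s, temp, "weight")

    def test_zero_delta_gives_pupariation_boundary(self, noiseless_truth,
                                                   published_isomorphen):
        models = {20.0: self.make_model(noiseless_truth, 20.0)}
        est = td.estimate_age_pupal(0.0, 20.0, models, published_isomorphen)
        assert est.point == pytest.approx(
            published_isomorphen.milestone_time("end_wandering", 20.0),
            abs=1e-6)

    def test_refusal_for_unreliable_low_temperature_model(
            self, published_isomorphen):
        bad = td.PupalIndicatorResults(
            temperature=15.0, indicator="weight",
            params=(-2.77e-5, 1.27e-7, -2.74e-10), bse=(0, 0, 0),
            r_squared=0.2896, time_range=(0.0, 800.0))
        with pytest.raises(td.UnreliableModelError, match="low temperature"):
            td.estimate_age_pupal(-0.005, 15.0, {15.0: bad},
                                  published_isomorphen)

    def test_roundtrip_recovers_known_intrapuparial_age(
            self, noiseless_truth, published_isomorphen):
        model = self.make_model(noiseless_truth, 25.0)
        delta = model.predict(120.0)
        est = td.estimate_age_pupal(delta, 25.0, {25.0: model},
                                    published_isomorphen)
        pre = published_isomorphen.milestone_time("end_wandering", 25.0)
        assert est.point - pre == pytest.approx(120.0, abs=0.5)


class TestCombine:
    def e(self, lo, hi, method="adh_milestone"):
        return td.PMIEstimate(point=(lo + hi) / 2, interval=(lo, hi),
                              method=method, inputs_digest="test")

    def test_single_estimate_unchanged(self):
        a = self.e(90, 110)
        assert td.combine_estimates([a]) is a

    def test_intersection_midpoint(self):
        c = td.combine_estimates([self.e(90, 110), self.e(100, 130)])
        assert c.interval == (100, 110)
        assert c.point == pytest.approx(105)
        assert not any("conflict" in w for w in c.warnings)

    def test_disjoint_intervals_union_with_conflict(self):
        c = td.combine_estimates([self.e(90, 100), self.e(120, 130)])
        assert c.interval == (90, 130)
        assert any("conflict" in w for w in c.warnings)

    def test_empty_input_rejected(self):
        with pytest.raises(td.ValidationError):
            td.combine_estimates([])


def test_estimate_validates_interval_ordering():
    with pytest.raises(td.ValidationError):
        td.PMIEstimate(point=5.0, interval=(10.0, 20.0), method="combined",
                       inputs_digest="bad")
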