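"""Synthetic-data generators: closed forms, determinism, noise structure."""

import numpy as np
import pandas as pd
import pytest

import thermodev as td


class TestGenerateCohort:
    def test_noiseless_closed_form(self):
        truth = td.SyntheticTruth(stage_params={"hatching": (300.0, 10.0)},
                                  sigma_duration=0.0)
        table = td.generate_cohort(truth, (15.0, 20.0, 25.0), 3, seed=0)
        means = table.groupby("temperature")["duration"].mean()
        assert means[15.0] == pytest.approx(60.0)
        assert means[20.0] == pytest.approx(30.0)
        assert means[25.0] == pytest.approx(20.0)

    def test_same_seed_identical(self, truth):
        a = td.generate_cohort(truth, (15.0, 20.0, 25.0), 3, seed=11)
        b = td.generate_cohort(truth, (15.0, 20.0, 25.0), 3, seed=11)
        pd.testing.assert_frame_equal(a, b)

    def test_different_seed_differs(self, truth):
        a = td.generate_cohort(truth, (15.0, 20.0, 25.0), 3, seed=11)
        b = td.generate_cohort(truth, (15.0, 20.0, 25.0), 3, seed=12)
        assert not a["duration"].equals(b["duration"])

    def test_adding_replicates_preserves_existing_draws(self, truth):
        small = td.generate_cohort(truth, (15.0, 20.0, 25.0), 3, seed=5)
        big = td.generate_cohort(truth, (15.0, 20.0, 25.0), 6, seed=5)
        merged = big.merge(small, on=["temperature", "replicate", "stage"],
                           suffixes=("_big", "_small"))
        assert len(merged) == len(small)
        np.testing.assert_allclose(merged["duration_big"],
                                   merged["duration_small"])

    def test_lognormal_mean_matches_theory(self):
        """Sample mean at 20 degC within 3 SE of K/(T-D0)*exp(sigma^2/2)."""
        sigma = 0.1
        truth = td.SyntheticTruth(stage_params={"hatching": (300.0, 10.0)},
                                  sigma_duration=sigma)
        table = td.generate_cohort(truth, (20.0,), 30, seed=3)
        d = table["duration"].to_numpy()
        expected = 30.0 * np.exp(sigma ** 2 / 2)
        se = d.std(ddof=1) / np.sqrt(len(d))
        assert abs(d.mean() - expected) < 3 * se

    def test_temperature_at_threshold_rejected(self):
        truth = td.SyntheticTruth(stage_params={"hatching": (300.0, 12.0)})
        with pytest.raises(td.ValidationError):
            td.generate_cohort(truth, (12.5, 20.0), 3, seed=0)

    def test_stage_durations_sum_to_totals(self, cohort):
        totals = td.total_durations(cohort)
        manual = cohort.groupby(["temperature", "replicate"])["duration"].sum()
        for row in totals.itertuples():
            assert row.total_duration == pytest.approx(
                manual[(row.temperature, row.replicate)])


class TestGenerateLengthSeries:
    def test_noiseless_monotone_nondecreasing(self, noiseless_truth):
        s = td.generate_length_series(noiseless_truth, 20.0, 12.0, seed=0)
        assert (np.diff(s["length"].to_numpy()) >= 0).all()

    def test_midpoint_is_half_maximum(self, noiseless_truth):
        T = 20.0
        t_mid = noiseless_truth.larval_midpoint(T)
        L = float(noiseless_truth.larval_length(t_mid, T))
        assert L == pytest.approx(noiseless_truth.L_max / 2, rel=1e-12)

    def test_warmer_reaches_every_length_earlier(self, noiseless_truth):
        """The isomegalen ordering holds already at generator level."""
        for L in (4.0, 8.0, 12.0, 16.0):
            times = []
            for T in (15.0, 20.0, 25.0):
                # invert the logistic analytically
                tau = (noiseless_truth.tau0
                       + np.log(L / (noiseless_truth.L_max - L))
                       / noiseless_truth.rho)
                times.append(tau / (T - noiseless_truth.D0_larval))
            assert times[0] > times[1] > times[2]

    def test_noiseless_cubic_fit_is_tight(self, noiseless_truth):
        s = td.generate_length_series(noiseless_truth, 20.0, 12.0, seed=0)
        model = td.fit_cubic_growth(s, 20.0)
        assert model.r_squared >= 0.99

    def test_times_start_at_zero(self, truth):
        s = td.generate_length_series(truth, 25.0, 12.0, seed=1)
        assert s["time"].iloc[0] == 0.0
        assert s["reference_event"].eq("hatching").all()


class TestGeneratePupalSeries:
    def test_noiseless_weight_strictly_decreasing_and_accelerating(
            self, noiseless_truth):
        s = td.generate_pupal_series(noiseless_truth, 20.0, 24.0, seed=0)
        w = s["weight"].to_numpy()
        assert (np.diff(w) < 0).all()
        # second derivative negative on a uniform grid: loss accelerates
        # toward eclosion (quadratic loss term, p = 2)
        t = np.arange(0.0, noiseless_truth.pupal_duration(20.0), 1.0)
        wu = noiseless_truth.pupal_weight(t, 20.0)
        assert (np.diff(wu, 2) < 1e-15).all()

    def test_initial_weight_is_w0(self, noiseless_truth):
        s = td.generate_pupal_series(noiseless_truth, 20.0, 24.0, seed=0)
        assert s["weight"].iloc[0] == pytest.approx(noiseless_truth.W0)

    def test_noiseless_dimensions_constant(self, noiseless_truth):
        s = td.generate_pupal_series(noiseless_truth, 20.0, 24.0, seed=0)
        assert s["length"].nunique() == 1
        assert s["width"].nunique() == 1

    def test_noiseless_length_cubic_coefficients_near_zero(self, noiseless_truth):
        s = td.generate_pupal_series(noiseless_truth, 20.0, 24.0, seed=0)
        model = td.fit_pupal_indicator(s, 20.0, "length")
        assert np.allclose(model.params, 0.0, atol=1e-12)

    def test_reference_event_is_pupariation(self, truth):
        s = td.generate_pupal_series(truth, 25.0, 24.0, seed=2)
        assert s["reference_event"].eq("pupariation").all()


class TestGenerateTemperatureLog:
    def test_constant_profile(self):
        log = td.generate_temperature_log(td.ConstantProfile(20.0), 48)
        assert len(log) == 49
        assert log["temperature"].min() == log["temperature"].max() == 20.0

    def test_sinusoid_bounds(self):
        log = td.generate_temperature_log(td.SinusoidProfile(15, 5, 24), 24)
        assert log["temperature"].min() >= 10.0 - 1e-12
        assert log["temperature"].max() <= 20.0 + 1e-12

    def test_whole_period_mean_matches(self):
        log = td.generate_temperature_log(td.SinusoidProfile(15, 5, 24), 240)
        t = log["time"].to_numpy()
        v = log["temperature"].to_numpy()
        mean = np.trapezoid(v, t) / (t[-1] - t[0])
        assert mean == pytest.approx(15.0, abs=1e-9)

    def test_subzero_profile_rejected(self):
        with pytest.raises(td.ValidationError):
            td.generate_temperature_log(td.SinusoidProfile(-10, 15, 24), 24)


def test_truth_validates_noise_and_exponent():
    with pytest.raises(td.ValidationError):
        td.SyntheticTruth(sigma_duration=-0.1)
    with pytest.raises(td.ValidationError):
        td.SyntheticTruth(accel_exponent=1.0)
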