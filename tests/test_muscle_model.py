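"""Activation cascade, bilinear force law, calibration and identification."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from workloop.muscle_model import (
    BILINEAR_TERMS,
    IdentificationDataset,
    MuscleParams,
    calibrate_activation_params,
    default_muscle_params,
    identify_bilinear_model,
    muscle_force,
    net_load_force,
    simulate_activation,
    twitch_response,
    twitch_times,
)


class TestActivationDynamics:
    def test_zero_input_stays_at_rest(self, muscle):
        tr = simulate_activation(muscle, ([0.0], [0.0]), horizon=1.0)
        assert np.allclose(tr["a"], 0.0) and np.allclose(tr["c"], 0.0)

    def test_step_response_matches_repeated_pole_closed_form(self, muscle):
        # equal time constants tau: a(t) = 1 - (1 + t/tau) exp(-t/tau)
        tau = muscle.tau_c
        assert muscle.tau_a == tau
        tr = simulate_activation(muscle, ([0.0], [1.0]), horizon=1.5, dt=1e-3)
        t = tr["time_s"].to_numpy()
        expected = 1.0 - (1.0 + t / tau) * np.exp(-t / tau)
        assert np.max(np.abs(tr["a"].to_numpy() - expected)) < 1e-6

    def test_steady_state_gain_is_unity(self, muscle):
        tr = simulate_activation(muscle, ([0.0], [0.6]), horizon=3.0)
        assert tr["a"].iloc[-1] == pytest.approx(0.6, abs=1e-6)

    @settings(deadline=None, max_examples=20, derandomize=True)
    @given(st.floats(0.1, 1.0), st.floats(0.05, 0.5))
    def test_linearity_and_time_invariance(self, scale, delay):
        m = default_muscle_params()
        base = simulate_activation(m, ([0.0, 0.1], [1.0, 0.0]), horizon=1.0, dt=1e-3)
        scaled = simulate_activation(m, ([0.0, 0.1], [scale, 0.0]), horizon=1.0, dt=1e-3)
        assert np.max(np.abs(scaled["a"] - scale * base["a"])) < 1e-9
        delay = round(delay, 3)  # align with the output grid
        shifted = simulate_activation(
            m, ([0.0, delay, delay + 0.1], [0.0, 1.0, 0.0]), horizon=1.0 + delay, dt=1e-3
        )
        n = base["a"].size
        k = int(round(delay / 1e-3))
        assert np.max(np.abs(
            shifted["a"].to_numpy()[k : k + n] - base["a"].to_numpy()[:n]
        )) < 1e-9

    @settings(deadline=None, max_examples=15, derandomize=True)
    @given(st.lists(st.floats(0.0, 1.0), min_size=3, max_size=8))
    def test_activation_bounded_in_unit_interval(self, levels):
        m = default_muscle_params()
        knots = np.arange(len(levels)) * 0.15
        tr = simulate_activation(m, (knots, levels), horizon=2.0)
        assert (tr["a"] >= -1e-12).all() and (tr["a"] <= 1 + 1e-12).all()
        assert (tr["c"] >= -1e-12).all() and (tr["c"] <= 1 + 1e-12).all()

    def test_rejects_nonfinite_stimulus(self, muscle):
        with pytest.raises(ValueError, match="non-finite"):
            simulate_activation(muscle, ([0.0, 0.1], [0.5, np.nan]), horizon=1.0)

    def test_rejects_negative_time_constants(self):
        with pytest.raises(ValueError, match="time constants"):
            MuscleParams(tau_c=-0.1)


class TestTwitchCalibration:
    def test_default_twitch_rise_is_125_ms(self, muscle):
        rise, fall = twitch_times(twitch_response(muscle))
        assert abs(rise - 0.125) < 1e-3
        assert fall > rise  # fall slower than rise for the repeated pole

    def test_equal_pole_impulse_peak_at_tau(self):
        # analytic argmax of t*exp(-t/tau) is t = tau
        tau_c, tau_a, info = calibrate_activation_params(0.125, 0.125)
        assert tau_c == pytest.approx(0.125, abs=1e-9)
        assert tau_a == pytest.approx(0.125, abs=1e-9)
        assert info["warning"]  # 125 ms fall is infeasible for this family

    def test_time_scale_invariance(self):
        t1 = calibrate_activation_params(0.125, 0.5)
        t2 = calibrate_activation_params(0.25, 1.0)
        assert t2[0] == pytest.approx(2 * t1[0], rel=1e-6)
        assert t2[1] == pytest.approx(2 * t1[1], rel=1e-6)

    def test_feasible_fall_target_is_matched(self):
        tau_c, tau_a, info = calibrate_activation_params(0.1, 0.6)
        assert not info["warning"]
        assert info["fall"] == pytest.approx(0.6, rel=1e-3)
        m = MuscleParams(tau_c=tau_c, tau_a=tau_a)
        rise, fall = twitch_times(twitch_response(m, horizon=3.0))
        assert abs(rise - 0.1) < 1e-3
        assert fall == pytest.approx(0.6, rel=0.02)

    def test_rejects_nonpositive_targets(self):
        with pytest.raises(ValueError):
            calibrate_activation_params(-0.1, 0.1)


class TestBilinearForce:
    def test_passive_line_at_zero_activation(self, muscle):
        f, k = muscle_force(muscle, muscle.l0, 0.0)
        assert f == pytest.approx(muscle.A + muscle.B * muscle.l0)
        assert k == pytest.approx(muscle.B)

    def test_stiffness_linear_in_activation(self, muscle):
        _, k0 = muscle_force(muscle, muscle.l0, 0.0)
        _, k1 = muscle_force(muscle, muscle.l0, 1.0)
        assert k1 - k0 == pytest.approx(muscle.D)

    def test_worked_arithmetic_example(self):
        m = MuscleParams(A=0.0, B=200.0, C=10.0, D=800.0, l0=0.01)
        f, _ = muscle_force(m, 0.01, 0.5)
        assert f == pytest.approx(11.0)

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(st.floats(0.024, 0.026), st.floats(0.1, 0.85), st.floats(1e-4, 1e-3),
           st.floats(0.01, 0.1))
    def test_exact_bilinearity_second_differences(self, l, a, dl, da):
        m = default_muscle_params()
        f = lambda ll, aa: muscle_force(m, ll, aa)[0]
        d2l = f(l + dl, a) - 2 * f(l, a) + f(l - dl, a)
        d2a = f(l, a + da) - 2 * f(l, a) + f(l, a - da)
        mixed = (f(l + dl, a + da) - f(l + dl, a) - f(l, a + da) + f(l, a)) / (dl * da)
        assert abs(d2l) < 1e-9
        assert abs(d2a) < 1e-9
        assert mixed == pytest.approx(m.D, rel=1e-6)

    def test_extrapolation_warns_not_fails(self, muscle):
        with pytest.warns(UserWarning, match="operating range"):
            muscle_force(muscle, muscle.l0 * 1.5, 0.2)

    def test_rejects_activation_outside_unit_interval(self, muscle):
        with pytest.raises(ValueError):
            muscle_force(muscle, muscle.l0, 1.5)


class TestNetLoadForce:
    def test_symmetric_muscles_balance_at_origin(self, muscle):
        f, _ = net_load_force(muscle, muscle, 0.0, 0.3, 0.3)
        assert f == pytest.approx(0.0, abs=1e-12)

    def test_coactivation_raises_stiffness_without_net_force(self, muscle):
        _, k_low = net_load_force(muscle, muscle, 0.0, 0.1, 0.1)
        f, k_high = net_load_force(muscle, muscle, 0.0, 0.8, 0.8)
        assert k_high > k_low
        assert f == pytest.approx(0.0, abs=1e-12)

    def test_net_stiffness_is_displacement_gradient(self, muscle):
        dx = 1e-6
        a1, a2 = 0.4, 0.7
        f_p, k = net_load_force(muscle, muscle, dx, a1, a2)
        f_m, _ = net_load_force(muscle, muscle, -dx, a1, a2)
        assert (f_p - f_m) / (2 * dx) == pytest.approx(-k, rel=1e-6)

    def test_agonist_only_arithmetic(self):
        m1 = MuscleParams(A=0.0, B=200.0, C=10.0, D=800.0, l0=0.01)
        m2 = MuscleParams(A=0.0, B=150.0, C=5.0, D=600.0, l0=0.012)
        f, _ = net_load_force(m1, m2, 0.0, 0.5, 0.0)
        assert f == pytest.approx(11.0 - (m2.A + m2.B * m2.l0))


def _make_dataset(m, n=2000, noise=0.0, seed=0, velocity_terms=(0.0, 0.0)):
    rng = np.random.default_rng(seed)
    l = m.l0 * (1 + rng.uniform(-0.08, 0.08, n))
    v = rng.uniform(-0.2, 0.2, n)
    a = rng.uniform(0.0, 1.0, n)
    E, F = velocity_terms
    force = m.A + m.B * l + a * (m.C + m.D * l) + E * v + F * a * v
    force = force + rng.normal(0.0, noise, n)
    return IdentificationDataset(pd.DataFrame({
        "time_s": np.arange(n) * 1e-3, "length_m": l, "velocity_m_s": v,
        "activation_est": a, "force_N": force,
    }))


class TestIdentification:
    def test_exact_recovery_on_noiseless_data(self, muscle):
        fit = identify_bilinear_model(_make_dataset(muscle), template=muscle)
        truth = {"offset": muscle.A, "length": muscle.B,
                 "activation": muscle.C, "activation_length": muscle.D}
        for term, val in truth.items():
            scale = max(abs(val), 1.0)
            assert abs(fit.coefficients[term] - val) / scale < 1e-8
        assert fit.variance_explained == pytest.approx(1.0, abs=1e-12)

    def test_noisy_recovery_within_three_standard_errors(self, muscle):
        # 5% of force RMS additive noise, 20 seeds
        ds0 = _make_dataset(muscle)
        rms = float(np.sqrt(np.mean(ds0.data["force_N"] ** 2)))
        truth = {"offset": muscle.A, "length": muscle.B,
                 "activation": muscle.C, "activation_length": muscle.D}
        failures = 0
        for seed in range(20):
            ds = _make_dataset(muscle, noise=0.05 * rms, seed=seed)
            fit = identify_bilinear_model(ds, template=muscle)
            assert fit.variance_explained > 0.95
            for term, val in truth.items():
                if abs(fit.coefficients[term] - val) > 3 * fit.stderr[term]:
                    failures += 1
        # ~1% chance per coefficient; allow a few across 80 draws
        assert failures <= 4

    def test_reduced_terms_robust_to_small_velocity_terms(self, muscle):
        ds = _make_dataset(muscle, velocity_terms=(0.1, 0.1))
        fit_red = identify_bilinear_model(ds, template=muscle)
        fit_full = identify_bilinear_model(
            ds, term_set=("offset", "length", "activation", "activation_length",
                          "velocity", "activation_velocity"))
        assert fit_full.variance_explained - fit_red.variance_explained < 0.01
        assert fit_red.variance_explained > 0.99

    def test_consistency_error_shrinks_with_sample_size(self, muscle):
        # root-n consistency: slope of log-error vs log-n near -1/2 over
        # three decades, error averaged over seeds to tame draw noise
        errs, ns = [], [100, 1000, 10000, 100000]
        for n in ns:
            e = []
            for seed in range(5):
                ds = _make_dataset(muscle, n=n, noise=0.1, seed=seed)
                fit = identify_bilinear_model(ds)
                e.append(abs(fit.coefficients["activation_length"] - muscle.D))
            errs.append(np.mean(e))
        slope = np.polyfit(np.log(ns), np.log(errs), 1)[0]
        assert -0.85 < slope < -0.2

    def test_rank_deficient_design_rejected(self, muscle):
        n = 200
        ds = _make_dataset(muscle, n=n)
        ds.data["length_m"] = muscle.l0  # no length excitation
        with pytest.raises(ValueError, match="rank-deficient"):
            identify_bilinear_model(ds)

    def test_holdout_variance_explained(self, muscle):
        fit = identify_bilinear_model(
            _make_dataset(muscle, noise=0.05, seed=2),
            holdout=_make_dataset(muscle, noise=0.05, seed=3),
        )
        assert 0.95 < fit.variance_explained <= 1.0


class TestParamsValidation:
    def test_muscles_only_pull(self):
        with pytest.raises(ValueError, match="pull"):
            MuscleParams(A=-10.0, B=10.0, C=0.0, D=0.0)

    def test_control_bounds_ordered(self):
        with pytest.raises(ValueError):
            MuscleParams(u_min=1.0, u_max=0.0)

    def test_dict_round_trip(self, muscle):
        assert MuscleParams.from_dict(muscle.to_dict()) == muscle
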