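"""Stimulation waveforms, emulated sessions, protocols and their statistics."""

import numpy as np
import pytest
from scipy import stats

from workloop.energetics import segment_cycles, Workloop, cyclic_work
from workloop.load_dynamics import PiecewiseControl, passive_equilibrium, simulate_coupled_system
from workloop.muscle_model import identify_bilinear_model
from workloop.experiment_emulation import (
    CONDITIONS_H2,
    SessionConfig,
    compare_ratio_test,
    contralateral_pair,
    emulate_workloop_session,
    generate_identification_dataset,
    generate_stim_waveform,
    planned_order,
    run_hypothesis1_protocol,
    run_hypothesis2_protocol,
    scanned_burst_schedule,
)


class TestStimWaveform:
    def test_pulse_count_follows_burst_duration(self):
        # burst of duration d at 200 Hz carries floor(d*200)+1 pulses
        w = generate_stim_waveform(2.0, [(0.0, 0.8 * np.pi)])
        d = 0.4 * w.period
        assert len(w.pulse_times(0)) == int(np.floor(d * 200.0)) + 1

    def test_empty_windows_zero_waveform(self):
        w = generate_stim_waveform(3.0, ([], []))
        t = np.linspace(0.0, 1.0, 2000)
        assert np.all(w.pulse_train(t, 0) == 0)
        u1, u2 = w.envelope_controls()
        assert np.all(u1(t) == 0) and np.all(u2(t) == 0)

    def test_waveform_periodicity_by_autocorrelation(self):
        w = generate_stim_waveform(2.5, [(0.3, 2.0)], pulse_width=2e-3)
        fs = 2000.0
        t = np.arange(0.0, 4.0, 1 / fs)
        x = w.pulse_train(t, 0) - np.mean(w.pulse_train(t, 0))
        ac = np.correlate(x, x, mode="full")[x.size - 1 :]
        lag = int(round(w.period * fs))
        window = ac[lag // 2 : 3 * lag // 2]
        assert np.argmax(window) + lag // 2 == lag

    def test_envelope_matches_windows(self):
        w = generate_stim_waveform(2.0, [(np.pi / 2, np.pi)])
        u1, _ = w.envelope_controls()
        assert u1(0.1) == 0.0    # before the burst (starts at T/4 = 0.125)
        assert u1(0.3) == 0.0    # after the burst ends at T/2 = 0.25
        assert u1(0.2) == 1.0    # inside [0.125, 0.25)
        assert u1(0.2 + w.period) == 1.0  # periodic

    def test_overlapping_windows_merged_with_warning(self):
        with pytest.warns(UserWarning, match="merged"):
            w = generate_stim_waveform(2.0, [(0.0, 1.0), (0.5, 2.0)])
        assert w.burst_windows[0] == [(0.0, 2.0)]

    def test_overlapping_pulses_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            generate_stim_waveform(2.0, [(0.0, 1.0)], pulse_rate=200.0,
                                   pulse_width=0.01)


class TestSessionEmulation:
    def test_zero_stimulation_no_motion_no_work(self, pair_muscles, load):
        cfg = SessionConfig(load=load, muscles=pair_muscles, repetitions=2,
                            cycles=3, force_noise_frac=0.0,
                            position_noise_frac=0.0, fatigue_rate=0.0)
        stim = generate_stim_waveform(2.0, ([], []))
        reps = emulate_workloop_session(cfg, stim, n_reps=2)
        assert abs(reps[0]["work_J"]) < 1e-12
        assert np.max(np.abs(reps[0]["trajectory"].v)) < 1e-10

    def test_noise_free_emulation_equals_direct_simulation(self, pair_muscles, load):
        cfg = SessionConfig(load=load, muscles=pair_muscles, repetitions=2,
                            cycles=4, force_noise_frac=0.0,
                            position_noise_frac=0.0, fatigue_rate=0.0)
        wins = ([(0.0, np.pi * 0.9)], [(np.pi, np.pi * 1.9)])
        stim = generate_stim_waveform(2.5, wins)
        rep = emulate_workloop_session(cfg, stim, n_reps=1)[0]
        u1, u2 = stim.envelope_controls()
        direct = simulate_coupled_system(
            pair_muscles, load, (u1, u2), passive_equilibrium(pair_muscles, load),
            horizon=cfg.cycles * stim.period, rtol=1e-7, atol=1e-9,
            nodes_per_cycle=200, cycle_period=stim.period,
        )
        assert np.array_equal(rep["trajectory"].states, direct.states)
        assert np.array_equal(rep["trajectory"].Fnet, direct.Fnet)

    def test_noise_applied_to_recorded_channels_only(self, pair_muscles, load):
        cfg = SessionConfig(load=load, muscles=pair_muscles, repetitions=2,
                            cycles=3, seed=5)
        stim = generate_stim_waveform(2.5, ([(0.0, 2.5)], []))
        rep = emulate_workloop_session(cfg, stim, n_reps=1)[0]
        assert not np.array_equal(rep["trajectory"].F1, rep["truth"].F1)
        assert np.array_equal(rep["trajectory"].states[:, 1:],
                              rep["truth"].states[:, 1:])

    def test_fatigue_decreases_work_across_repetitions(self, pair_muscles, load):
        # expectation over 20 seeds: later repetitions do less work
        deltas = []
        for seed in range(20):
            cfg = SessionConfig(load=load, muscles=pair_muscles, repetitions=2,
                                cycles=3, fatigue_rate=0.05, seed=seed)
            stim = generate_stim_waveform(2.5, ([(0.0, 2.5)], []))
            reps = emulate_workloop_session(cfg, stim, n_reps=3)
            works = [r["work_J"] for r in reps]
            deltas.append(works[0] - works[-1])
        assert np.mean(deltas) > 0
        assert np.mean(np.array(deltas) > 0) >= 0.9

    def test_negative_noise_rejected(self, pair_muscles, load):
        with pytest.raises(ValueError):
            SessionConfig(load=load, muscles=pair_muscles,
                          force_noise_frac=-0.1)

    def test_discard_first_is_noop_on_preconverged_cycles(self, solution_single_24):
        # tile the converged periodic cycle: averages with and without the
        # first cycle coincide
        traj = solution_single_24.trajectory
        T = traj.t[-1]
        n = traj.t.size - 1
        t3 = np.concatenate([traj.t[:-1] + k * T for k in range(3)] + [[3 * T]])
        F3 = np.concatenate([traj.Fnet[:-1]] * 3 + [traj.Fnet[-1:]])
        x3 = np.concatenate([traj.x[:-1]] * 3 + [traj.x[-1:]])
        cycles = segment_cycles(t3, T)
        keep_all = cyclic_work(Workloop(force=F3, displacement=x3, cycles=cycles))
        drop_first = cyclic_work(Workloop(force=F3, displacement=x3, cycles=cycles[1:]))
        assert keep_all["work_J"] == pytest.approx(drop_first["work_J"], rel=1e-9)


class TestIdentificationPipeline:
    def test_round_trip_recovery_noise_free(self, muscle):
        ds = generate_identification_dataset(muscle)
        fit = identify_bilinear_model(ds, template=muscle)
        truth = {"offset": muscle.A, "length": muscle.B,
                 "activation": muscle.C, "activation_length": muscle.D}
        for term, val in truth.items():
            assert abs(fit.coefficients[term] - val) / max(abs(val), 1.0) < 1e-8

    def test_design_conditioning_improves_with_richer_excitation(self, muscle):
        def cond(freqs, amps):
            ds = generate_identification_dataset(muscle, frequencies=freqs,
                                                 amplitudes=amps)
            d = ds.data
            X = np.column_stack([
                np.ones(len(d)), d["length_m"], d["activation_est"],
                d["activation_est"] * d["length_m"],
            ])
            return np.linalg.cond(X / np.linalg.norm(X, axis=0))

        c2 = cond((1.0, 2.0), (0.001, 0.002))
        c4 = cond((1.0, 2.0, 4.0, 6.0), (0.001, 0.002, 0.003))
        assert c4 <= c2

    def test_noisy_recovery_with_monte_carlo(self, muscle):
        fails = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            ds = generate_identification_dataset(muscle, noise_sd=0.05, rng=rng)
            fit = identify_bilinear_model(ds, template=muscle)
            assert fit.variance_explained > 0.95
            if abs(fit.coefficients["activation_length"] - muscle.D) > \
                    4 * fit.stderr["activation_length"]:
                fails += 1
        assert fails <= 1

    def test_requires_multiple_frequencies_and_amplitudes(self, muscle):
        with pytest.raises(ValueError, match="identifiability"):
            generate_identification_dataset(muscle, frequencies=(2.0,),
                                            amplitudes=(0.001, 0.002))


class TestStatistics:
    def test_samples_at_threshold_give_null_result(self):
        out = compare_ratio_test([2.0, 2.0, 2.0], 2.0)
        assert out["t"] == 0.0 and out["p"] == 1.0
        assert out["degenerate_variance"]

    def test_location_invariance(self, rng):
        x = rng.normal(1.5, 0.3, 8)
        a = compare_ratio_test(x, 1.0)
        b = compare_ratio_test(x + 2.5, 3.5)
        assert a["t"] == pytest.approx(b["t"], rel=1e-12)
        assert a["p"] == pytest.approx(b["p"], rel=1e-12)

    def test_monte_carlo_power_at_half_sigma_shift(self):
        # threshold + N(0.5, 0.1^2), n = 6: p < 0.01 nearly always
        rng = np.random.default_rng(99)
        hits = 0
        for _ in range(1000):
            x = 2.0 + rng.normal(0.5, 0.1, 6)
            if compare_ratio_test(x, 2.0)["p"] < 0.01:
                hits += 1
        assert hits >= 950

    def test_ordering_uniformly_distributed(self):
        # chi-square over 10^4 planned orderings of three conditions
        rng = np.random.default_rng(3)
        counts = {}
        for _ in range(10000):
            key = tuple(planned_order(rng, CONDITIONS_H2))
            counts[key] = counts.get(key, 0) + 1
        assert len(counts) == 6
        chi2, p = stats.chisquare(list(counts.values()))
        assert p > 0.01


@pytest.fixture(scope="module")
def fast_cfg(load):
    m = contralateral_pair(
        __import__("workloop").default_muscle_params(),
        np.random.default_rng(11),
    )
    return SessionConfig(load=load, muscles=m, frequencies=(2.0, 2.5, 3.0),
                         repetitions=3, seed=4)


def _fast_provider(cfg, single):
    muscles = (cfg.muscles[0], cfg.muscles[1].zeroed()) if single else cfg.muscles

    def provider(freq):
        return scanned_burst_schedule(muscles, cfg.load, freq)[0]

    return provider


class TestProtocols:
    def test_hypothesis1_normalized_power_ordering(self, fast_cfg):
        res = run_hypothesis1_protocol(fast_cfg,
                                       schedule_provider=_fast_provider(fast_cfg, True))
        summary = res.stats["summary"]
        assert summary[2.0]["mean"] == 1.0 and summary[2.0]["sd"] == 0.0
        assert res.stats["p_opt_vs_1"]["mean"] > 1.0
        assert summary[2.5]["mean"] > summary[3.0]["mean"]
        # each set's ordering is a permutation of the planned conditions
        for order in res.ordering:
            assert sorted(order) == [2.0, 2.5, 3.0]

    def test_hypothesis2_synergy_above_two_at_2p5(self, fast_cfg):
        res = run_hypothesis2_protocol(fast_cfg, 2.5,
                                       schedule_provider=_fast_provider(fast_cfg, False))
        S = np.asarray(res.stats["S_values"])
        assert S.size == fast_cfg.repetitions
        assert S.mean() > 2.0
        for order in res.ordering:
            assert sorted(order) == sorted(CONDITIONS_H2)

    def test_impedance_free_surrogates_synergy_two(self, load):
        # D = 0 surrogate muscles: S = 2 within the noise of the emulation
        from workloop.muscle_model import MuscleParams

        m0 = MuscleParams(A=0.0, B=0.0, C=1.0, D=0.0, l0=0.025)
        cfg = SessionConfig(load=load, muscles=(m0, m0), repetitions=3,
                            cycles=10, force_noise_frac=0.0,
                            position_noise_frac=0.0, fatigue_rate=0.0, seed=8)
        res = run_hypothesis2_protocol(cfg, 2.0,
                                       schedule_provider=_fast_provider(cfg, False))
        S = np.asarray(res.stats["S_values"])
        assert np.all(np.abs(S - 2.0) < 0.15)
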