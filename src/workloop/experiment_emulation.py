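"""Emulation of virtual-load workloop experiments on synthetic muscles.

Reproduces, end to end and without any hardware, the structure of in vitro
sessions in which explanted muscles drive an emulated mass-spring-damper
load through force-measuring servos: phase-triggered stimulation waveforms
(200 Hz trains of 100 µs pulses during active bursts), repetitions with
randomized condition ordering, seven-cycle measurements with the first
cycle discarded, additive measurement noise on recorded force and position,
and a slow multiplicative fatigue drift of the active force coefficients.

The stimulation pulse rate is far above the activation cascade bandwidth
(1/tau ~ 8 Hz), so a 200 Hz train produces a fused, fully recruited
contraction; the model input is therefore the burst recruitment envelope
(u = 1 within bursts), while the pulse train itself is exposed for
waveform-level analyses.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .energetics import cyclic_work, segment_cycles, Workloop, SynergyMeasurement
from .load_dynamics import (
    LoadParams,
    PiecewiseControl,
    Trajectory,
    default_load_params,
    passive_equilibrium,
    simulate_coupled_system,
)
from .muscle_model import (
    IdentificationDataset,
    MuscleParams,
    default_muscle_params,
    muscle_force,
    twitch_response,
)
from .optimal_control import (
    OptimalControlProblem,
    burst_control,
    solve_cyclic_optimal_control,
)

__all__ = [
    "StimWaveform",
    "SessionConfig",
    "ProtocolResult",
    "generate_stim_waveform",
    "emulate_workloop_session",
    "generate_identification_dataset",
    "run_hypothesis1_protocol",
    "run_hypothesis2_protocol",
    "compare_ratio_test",
    "optimal_burst_schedule",
    "scanned_burst_schedule",
]

TWO_PI = 2 * np.pi


def _merge_windows(windows: Sequence[tuple[float, float]]) -> list[tuple[float, float]]:
    """Merge overlapping phase windows (radians in [0, 2π))."""
    if not windows:
        return []
    for lo, hi in windows:
        if not (0 <= lo < TWO_PI) or not (0 < hi <= TWO_PI) or hi <= lo:
            raise ValueError("burst windows must satisfy 0 <= lo < hi <= 2*pi")
    srt = sorted(windows)
    merged = [list(srt[0])]
    overlap = False
    for lo, hi in srt[1:]:
        if lo <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], hi)
            overlap = True
        else:
            merged.append([lo, hi])
    if overlap:
        warnings.warn("overlapping burst windows merged")
    return [tuple(w) for w in merged]


@dataclass
class StimWaveform:
    """Periodic stimulation waveform for an agonist/antagonist pair.

    ``burst_windows`` holds, per muscle, phase intervals (radians) of the
    oscillation cycle during which the muscle receives a pulse train at
    ``pulse_rate`` (Hz) with pulses of ``pulse_width`` (s).
    """

    frequency: float
    burst_windows: tuple[list[tuple[float, float]], list[tuple[float, float]]]
    pulse_rate: float = 200.0
    pulse_width: float = 100e-6
    amplitude: float = 1.0

    def __post_init__(self) -> None:
        if self.frequency <= 0:
            raise ValueError("frequency must be positive")
        if self.pulse_rate * self.pulse_width >= 1:
            raise ValueError("pulses overlap: require pulse_rate*pulse_width < 1")
        self.burst_windows = tuple(_merge_windows(w) for w in self.burst_windows)

    @property
    def period(self) -> float:
        return 1.0 / self.frequency

    def pulse_times(self, muscle: int, n_cycles: int = 1) -> np.ndarray:
        """Pulse onset times (s) over ``n_cycles`` oscillation cycles."""
        T = self.period
        step = 1.0 / self.pulse_rate
        times = []
        for cyc in range(n_cycles):
            for lo, hi in self.burst_windows[muscle]:
                t0, t1 = lo / TWO_PI * T, hi / TWO_PI * T
                n_p = int(np.floor((t1 - t0) / step + 1e-9)) + 1
                times.extend(cyc * T + t0 + np.arange(n_p) * step)
        return np.asarray(times)

    def pulse_train(self, t: np.ndarray, muscle: int) -> np.ndarray:
        """Sampled pulse-train value (amplitude inside pulses, else 0)."""
        t = np.asarray(t, dtype=float)
        T = self.period
        out = np.zeros_like(t)
        pulses = self.pulse_times(muscle, 1)
        tt = np.mod(t, T)
        for p in pulses:
            out[(tt >= p) & (tt < p + self.pulse_width)] = self.amplitude
        return out

    def envelope_controls(self) -> tuple[PiecewiseControl, PiecewiseControl]:
        """Recruitment-envelope controls (u = amplitude inside bursts)."""
        T = self.period
        out = []
        for wins in self.burst_windows:
            knots, vals = [0.0], [0.0]
            for lo, hi in wins:
                t0, t1 = lo / TWO_PI * T, hi / TWO_PI * T
                if t0 == 0.0:
                    vals[0] = self.amplitude
                else:
                    knots += [t0]
                    vals += [self.amplitude]
                if t1 < T:
                    knots += [t1]
                    vals += [0.0]
            out.append(PiecewiseControl(knots, vals, period=T))
        return tuple(out)


def generate_stim_waveform(
    frequency: float,
    burst_windows,
    pulse_rate: float = 200.0,
    pulse_width: float = 100e-6,
    amplitude: float = 1.0,
) -> StimWaveform:
    """Build a periodic stimulation waveform from burst phase windows.

    ``burst_windows`` is either a pair of window lists (two muscles) or a
    single list (agonist only).
    """
    if burst_windows and isinstance(burst_windows[0], tuple) and np.isscalar(burst_windows[0][0]):
        burst_windows = (list(burst_windows), [])
    w1, w2 = burst_windows
    return StimWaveform(frequency=frequency, burst_windows=(list(w1), list(w2)),
                        pulse_rate=pulse_rate, pulse_width=pulse_width,
                        amplitude=amplitude)


# ---------------------------------------------------------------------------
# burst schedules
# ---------------------------------------------------------------------------


def _windows_from_control(u: np.ndarray, t: np.ndarray, T: float,
                          pulse_rate: float) -> list[tuple[float, float]]:
    """Phase windows where u > 0.5, quantized to the pulse grid."""
    on = u > 0.5
    if not on.any():
        return []
    edges = np.diff(on.astype(int))
    starts = list(t[1:][edges == 1])
    stops = list(t[1:][edges == -1])
    if on[0]:
        starts = [t[0]] + starts
    if on[-1]:
        stops = stops + [T]
    q = 1.0 / pulse_rate
    wins = []
    for s, e in zip(starts, stops):
        s, e = np.round(s / q) * q, np.round(e / q) * q
        if e - s >= q / 2:
            wins.append((s / T * TWO_PI, min(e / T * TWO_PI, TWO_PI)))
    # wrap-around burst: merge last-with-first handled by _merge_windows
    return wins


def optimal_burst_schedule(
    muscles: tuple[MuscleParams, MuscleParams],
    load: LoadParams,
    frequency: float,
    pulse_rate: float = 200.0,
    warm: "object | None" = None,
):
    """Burst windows from the cyclic power-optimal control solution.

    Mirrors the experimental procedure: the active segments of the
    stimulation waveform are the bang-bang on-intervals of the optimal
    control at the session frequency, quantized to the pulse grid.
    """
    problem = OptimalControlProblem(muscles=muscles, load=load, frequency=frequency)
    sol = solve_cyclic_optimal_control(problem, init=warm)
    T = 1.0 / frequency
    wins = tuple(
        _windows_from_control(sol.trajectory.u[:, i], sol.trajectory.t, T, pulse_rate)
        for i in range(2)
    )
    return wins, sol


def scanned_burst_schedule(
    muscles: tuple[MuscleParams, MuscleParams],
    load: LoadParams,
    frequency: float,
    duty: float = 0.45,
    n_phases: int = 8,
    antiphase: bool | None = None,
):
    """Cheap burst schedule: fixed duty, burst phase chosen by a work scan.

    A forward-simulation stand-in for the optimal-control schedule, useful
    when many conditions are needed quickly.
    """
    if antiphase is None:
        antiphase = muscles[1].C != 0 or muscles[1].D != 0
    best, best_phase = -np.inf, 0.0
    init = passive_equilibrium(muscles, load)
    for ph in np.arange(n_phases) / n_phases:
        u1 = burst_control(frequency, ph, duty)
        u2 = (burst_control(frequency, ph + 0.5, duty) if antiphase
              else PiecewiseControl([0.0], [0.0]))
        traj = simulate_coupled_system(muscles, load, (u1, u2), init,
                                       horizon=4 / frequency, rtol=1e-6, atol=1e-8,
                                       nodes_per_cycle=120, cycle_period=1 / frequency)
        mask = traj.t >= traj.t[-1] - 1 / frequency
        w = float(np.trapezoid(traj.Fnet[mask] * traj.v[mask], traj.t[mask]))
        if w > best:
            best, best_phase = w, ph
    w1 = [(best_phase * TWO_PI, min((best_phase + duty) * TWO_PI, TWO_PI))]
    if best_phase + duty > 1:
        w1 = [(best_phase * TWO_PI, TWO_PI), (0.0, (best_phase + duty - 1) * TWO_PI)]
    wins2 = []
    if antiphase:
        p2 = (best_phase + 0.5) % 1.0
        if p2 + duty <= 1:
            wins2 = [(p2 * TWO_PI, (p2 + duty) * TWO_PI)]
        else:
            wins2 = [(p2 * TWO_PI, TWO_PI), (0.0, (p2 + duty - 1) * TWO_PI)]
    return (w1, wins2), None


# ---------------------------------------------------------------------------
# sessions
# ---------------------------------------------------------------------------


@dataclass
class SessionConfig:
    """Configuration of an emulated workloop session."""

    load: LoadParams = field(default_factory=default_load_params)
    muscles: tuple[MuscleParams, MuscleParams] | None = None
    frequencies: tuple[float, ...] = (2.0, 2.5, 3.0)
    repetitions: int = 6
    cycles: int = 7
    discard_first: bool = True
    force_noise_frac: float = 0.02    # SD as a fraction of peak recorded force
    position_noise_frac: float = 0.001  # SD as a fraction of excursion
    fatigue_rate: float = 0.01        # per-measurement decay of active coefficients
    seed: int = 0

    def __post_init__(self) -> None:
        if self.muscles is None:
            m = default_muscle_params()
            self.muscles = (m, m)
        if self.repetitions < 2:
            raise ValueError("need >= 2 repetitions for any statistical output")
        if self.force_noise_frac < 0 or self.position_noise_frac < 0:
            raise ValueError("noise SDs must be non-negative")
        if not (0 <= self.fatigue_rate < 1):
            raise ValueError("fatigue rate must lie in [0, 1)")

    def config_hash(self) -> str:
        blob = json.dumps(
            {
                "load": self.load.to_dict(),
                "muscles": [m.to_dict() for m in self.muscles],
                "frequencies": list(self.frequencies),
                "repetitions": self.repetitions,
                "cycles": self.cycles,
                "discard_first": self.discard_first,
                "force_noise_frac": self.force_noise_frac,
                "position_noise_frac": self.position_noise_frac,
                "fatigue_rate": self.fatigue_rate,
            },
            sort_keys=True,
        )
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


@dataclass
class ProtocolResult:
    """Per-repetition measurements of a protocol plus summary statistics."""

    table: pd.DataFrame
    ordering: list
    stats: dict
    seed: int
    config_hash: str
    n_excluded: int = 0

    def to_csv(self, path) -> None:
        out = self.table.copy()
        out["seed"] = self.seed          # provenance embedded in every file
        out["config_hash"] = self.config_hash
        out.to_csv(path, index=False)


def _measure_repetition(
    cfg: SessionConfig,
    stim: StimWaveform,
    fatigue_scale: float,
    rng: np.random.Generator,
    mute: tuple[bool, bool] = (False, False),
) -> dict:
    """Run one measurement: simulate, add noise, reduce to work/power."""
    m1, m2 = cfg.muscles
    m1f, m2f = m1.fatigued(fatigue_scale), m2.fatigued(fatigue_scale)
    u1, u2 = stim.envelope_controls()
    if mute[0]:
        u1 = PiecewiseControl([0.0], [0.0])
    if mute[1]:
        u2 = PiecewiseControl([0.0], [0.0])
    muscles = (m1f, m2f)
    init = passive_equilibrium(muscles, cfg.load)
    T = stim.period
    traj = simulate_coupled_system(
        muscles, cfg.load, (u1, u2), init, horizon=cfg.cycles * T,
        rtol=1e-7, atol=1e-9, nodes_per_cycle=200, cycle_period=T,
    )
    # measurement noise on recorded channels only; ground truth retained
    f_sd = cfg.force_noise_frac * max(np.max(np.abs(traj.F1)), np.max(np.abs(traj.F2)))
    x_sd = cfg.position_noise_frac * max(np.ptp(traj.x), 1e-12)
    n = traj.t.size
    F1n = traj.F1 + rng.normal(0.0, f_sd, n) if f_sd > 0 else traj.F1.copy()
    F2n = traj.F2 + rng.normal(0.0, f_sd, n) if f_sd > 0 else traj.F2.copy()
    xn = traj.x + rng.normal(0.0, x_sd, n) if x_sd > 0 else traj.x.copy()
    noisy = Trajectory(
        t=traj.t.copy(),
        states=np.column_stack([xn, traj.states[:, 1:]]),
        u=traj.u.copy(), F1=F1n, F2=F2n, Fnet=F1n - F2n,
        muscles=muscles, load=cfg.load,
        meta={"fatigue_scale": fatigue_scale, "noisy": True},
    )
    cycles = segment_cycles(noisy.t, T)
    if cfg.discard_first:
        cycles = cycles[1:]
    loop = Workloop(force=noisy.Fnet, displacement=noisy.x, cycles=cycles)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        # sessions average all recorded cycles after the discard; the early
        # cycles are legitimately open while the system converges from rest
        cw = cyclic_work(loop, frequency=stim.frequency, closure_tol=np.inf)
    return {
        "trajectory": noisy,
        "truth": traj,
        "work_J": cw["work_J"],
        "power_W": cw["mean_power_W"],
        "fatigue_scale": fatigue_scale,
    }


def emulate_workloop_session(
    cfg: SessionConfig,
    stim: StimWaveform,
    n_reps: int | None = None,
    rng: np.random.Generator | None = None,
    fatigue_start: int = 0,
    mute: tuple[bool, bool] = (False, False),
) -> list[dict]:
    """Repeated noisy measurements of one condition.

    Fatigue multiplies the active force coefficients by
    ``(1 - fatigue_rate)`` per measurement, starting from measurement index
    ``fatigue_start``.  With zero noise and zero fatigue the recorded
    traces equal the direct simulation exactly.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    n_reps = cfg.repetitions if n_reps is None else n_reps
    out = []
    for r in range(n_reps):
        scale = (1.0 - cfg.fatigue_rate) ** (fatigue_start + r)
        out.append(_measure_repetition(cfg, stim, scale, rng, mute=mute))
    return out


# ---------------------------------------------------------------------------
# identification datasets
# ---------------------------------------------------------------------------


def generate_identification_dataset(
    muscle: MuscleParams,
    frequencies: Sequence[float] = (1.0, 2.0, 3.0, 4.0, 5.0, 6.0),
    amplitudes: Sequence[float] = (0.001, 0.002),
    trigger_phases: Sequence[float] = (0.0, np.pi),
    noise_sd: float = 0.0,
    n_cycles: int = 3,
    fs: float = 500.0,
    rng: np.random.Generator | None = None,
) -> IdentificationDataset:
    """Synthesize a model-identification dataset from imposed oscillations.

    Sinusoidal length trajectories (motion-source mode: the motion is
    imposed regardless of contractile force) are applied at each frequency
    and amplitude; a stimulus is triggered at each listed phase once per
    cycle, and the activation estimate is the superposition of normalized
    twitch profiles — the same construction used on the measured side, so
    zero-noise data are exactly consistent with the bilinear force law.
    """
    if len(frequencies) < 2 or len(amplitudes) < 2:
        raise ValueError("need >= 2 frequencies and >= 2 amplitudes for identifiability")
    if rng is None:
        rng = np.random.default_rng(0)
    tw = twitch_response(muscle, horizon=2.0, dt=1.0 / fs)
    h = tw["a"].to_numpy()
    h = h / h.max()
    frames = []
    for f in frequencies:
        T = 1.0 / f
        t = np.arange(0.0, n_cycles * T, 1.0 / fs)
        for amp in amplitudes:
            length = muscle.l0 + amp * np.sin(TWO_PI * f * t)
            velocity = amp * TWO_PI * f * np.cos(TWO_PI * f * t)
            a_est = np.zeros_like(t)
            for phase in trigger_phases:
                for cyc in range(n_cycles):
                    t_trig = (cyc + phase / TWO_PI) * T
                    idx = int(np.round(t_trig * fs))
                    if idx < t.size:
                        seg = min(h.size, t.size - idx)
                        a_est[idx : idx + seg] += h[:seg]
            a_est = np.clip(a_est, 0.0, 1.0)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                force, _ = muscle_force(muscle, length, a_est)
            if noise_sd > 0:
                force = force + rng.normal(0.0, noise_sd, force.shape)
            frames.append(pd.DataFrame({
                "time_s": t, "length_m": length, "velocity_m_s": velocity,
                "activation_est": a_est, "force_N": force,
                "freq_Hz": f, "amplitude_m": amp,
            }))
    data = pd.concat(frames, ignore_index=True)
    meta = {
        "frequencies_Hz": list(frequencies),
        "amplitudes_m": list(amplitudes),
        "trigger_phases_rad": list(trigger_phases),
        "noise_sd_N": noise_sd,
    }
    return IdentificationDataset(data=data[[
        "time_s", "length_m", "velocity_m_s", "activation_est", "force_N"
    ]], metadata=meta)


# ---------------------------------------------------------------------------
# hypothesis protocols
# ---------------------------------------------------------------------------


def compare_ratio_test(samples: Sequence[float], threshold: float) -> dict:
    """One-sample two-sided t-test of the sample mean against a threshold.

    Stars follow the figure-annotation convention: (**) for p < 0.01, (*)
    for p < 0.05.  Zero-variance samples are reported with p = 1 when the
    mean equals the threshold and p = 0 otherwise, flagged degenerate.
    """
    x = np.asarray(samples, dtype=float)
    if x.size < 2:
        raise ValueError("need >= 2 samples")
    sd = x.std(ddof=1)
    if sd == 0:
        equal = bool(np.isclose(x.mean(), threshold))
        return {
            "t": 0.0 if equal else np.inf * np.sign(x.mean() - threshold),
            "p": 1.0 if equal else 0.0,
            "mean": float(x.mean()), "sd": 0.0, "n": int(x.size),
            "stars": "" if equal else "**", "degenerate_variance": True,
        }
    t, p = stats.ttest_1samp(x, threshold)
    stars = "**" if p < 0.01 else ("*" if p < 0.05 else "")
    return {"t": float(t), "p": float(p), "mean": float(x.mean()),
            "sd": float(sd), "n": int(x.size), "stars": stars,
            "degenerate_variance": False}


def planned_order(rng: np.random.Generator, conditions: Sequence) -> list:
    """Uniformly random ordering of the conditions of one measurement set."""
    return [conditions[i] for i in rng.permutation(len(conditions))]


def _default_schedule_provider(cfg: SessionConfig):
    cache: dict[float, tuple] = {}

    def provider(freq: float):
        if freq not in cache:
            cache[freq] = optimal_burst_schedule(cfg.muscles, cfg.load, freq)[0]
        return cache[freq]

    return provider


def run_hypothesis1_protocol(
    cfg: SessionConfig,
    schedule_provider: Callable | None = None,
) -> ProtocolResult:
    """Single-muscle power at {f_n, f_opt, f_high}, normalized per set.

    Each measurement set visits the three frequencies in randomized order
    (to decorrelate the fatigue drift from the conditions); per-repetition
    power is the average of the recorded cycles with the first discarded,
    normalized by the set's own P(f_n).  Tests: normalized P(f_opt) vs 1,
    and P(f_opt) - P(f_high) vs 0.
    """
    freqs = sorted(cfg.frequencies)
    if len(freqs) != 3:
        raise ValueError("hypothesis 1 needs exactly three frequencies")
    f_n, f_opt, f_high = freqs
    if abs(f_n - cfg.load.f_n) > 0.5:
        warnings.warn("lowest protocol frequency is far from the load f_n")
    # single-muscle sessions have no antagonist attached at all
    cfg = replace(cfg, muscles=(cfg.muscles[0], cfg.muscles[1].zeroed()))
    if schedule_provider is None:
        schedule_provider = _default_schedule_provider(cfg)
    rng = np.random.default_rng(cfg.seed)
    rows, ordering = [], []
    counter = 0
    for s in range(cfg.repetitions):
        order = planned_order(rng, freqs)
        ordering.append(order)
        for f in order:
            wins = schedule_provider(f)
            stim = generate_stim_waveform(f, (wins[0], []))
            scale = (1.0 - cfg.fatigue_rate) ** counter
            meas = _measure_repetition(cfg, stim, scale, rng, mute=(False, True))
            rows.append({"set_id": s, "freq_Hz": f, "work_J": meas["work_J"],
                         "power_W": meas["power_W"], "order_index": order.index(f),
                         "fatigue_scale": scale})
            counter += 1
    table = pd.DataFrame(rows)
    from .energetics import normalized_power_table

    npt = normalized_power_table(table, f_n)
    tab = npt["table"].merge(table, on=["set_id", "freq_Hz", "power_W"])
    p_opt = tab[tab.freq_Hz == f_opt].sort_values("set_id")["normalized_power"].to_numpy()
    p_high = tab[tab.freq_Hz == f_high].sort_values("set_id")["normalized_power"].to_numpy()
    stats_out = {
        "summary": npt["summary"],
        "p_opt_vs_1": compare_ratio_test(p_opt, 1.0),
        "p_opt_minus_p_high_vs_0": compare_ratio_test(p_opt - p_high, 0.0),
    }
    return ProtocolResult(table=tab, ordering=ordering, stats=stats_out,
                          seed=cfg.seed, config_hash=cfg.config_hash())


CONDITIONS_H2 = ("agonist", "antagonist", "both")


def contralateral_pair(
    base: MuscleParams, rng: np.random.Generator, spread: float = 0.05
) -> tuple[MuscleParams, MuscleParams]:
    """Antagonist drawn as the agonist perturbed by ~5% (contralateral pair)."""
    eps = rng.normal(0.0, spread)
    m2 = replace(base, B=base.B * (1 + eps), C=base.C * (1 + eps), D=base.D * (1 + eps))
    return base, m2


def run_hypothesis2_protocol(
    cfg: SessionConfig,
    frequency: float,
    schedule_provider: Callable | None = None,
) -> ProtocolResult:
    """Synergy sets {W1, W2, W12} at one oscillation frequency.

    Each set measures agonist-only, antagonist-only, and both-muscle
    conditions in randomized order (bursts from the optimal-control
    schedule by default) and forms S = W12/(W1+W2); S is tested against
    the impedance-free value 2.  Sets with W1 + W2 <= 0 are excluded with
    a warning.
    """
    if schedule_provider is None:
        schedule_provider = _default_schedule_provider(cfg)
    rng = np.random.default_rng(cfg.seed)
    wins = schedule_provider(frequency)
    stim = generate_stim_waveform(frequency, wins)
    rows, ordering = [], []
    counter = 0
    for s in range(cfg.repetitions):
        order = planned_order(rng, CONDITIONS_H2)
        ordering.append(order)
        works = {}
        for cond in order:
            mute = {"agonist": (False, True), "antagonist": (True, False),
                    "both": (False, False)}[cond]
            scale = (1.0 - cfg.fatigue_rate) ** counter
            meas = _measure_repetition(cfg, stim, scale, rng, mute=mute)
            works[cond] = meas
            rows.append({"set_id": s, "condition": cond, "freq_Hz": frequency,
                         "work_J": meas["work_J"], "power_W": meas["power_W"],
                         "order_index": order.index(cond), "fatigue_scale": scale})
            counter += 1
        m = SynergyMeasurement(W1=works["agonist"]["work_J"],
                               W2=works["antagonist"]["work_J"],
                               W12=works["both"]["work_J"])
        if m.W1 + m.W2 <= 0:
            warnings.warn(f"set {s}: W1 + W2 <= 0, synergy ratio excluded")
            ratio = np.nan
        else:
            ratio = m.ratio
        for row in rows[-3:]:
            row["ratio_S"] = ratio
    table = pd.DataFrame(rows)
    ratios = table.groupby("set_id")["ratio_S"].first().dropna().to_numpy()
    n_excluded = cfg.repetitions - ratios.size
    stats_out = {"S_vs_2": compare_ratio_test(ratios, 2.0) if ratios.size >= 2 else None,
                 "S_values": ratios.tolist()}
    return ProtocolResult(table=table, ordering=ordering, stats=stats_out,
                          seed=cfg.seed, config_hash=cfg.config_hash(),
                          n_excluded=n_excluded)
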