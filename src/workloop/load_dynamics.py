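"""Mass-spring-damper load, its impedance, and the coupled muscle–load system.

The load is a single-DOF linear second-order system, M*x'' + b*x' + k*x =
F_net, driven by the net force of an agonist/antagonist muscle pair.  The
coupled system has six states: (x, v, a1, c1, a2, c2).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .muscle_model import MuscleParams, muscle_force

__all__ = [
    "LoadParams",
    "SystemState",
    "Trajectory",
    "default_load_params",
    "simulate_coupled_system",
    "load_impedance",
    "steady_state_periodic_response",
    "PiecewiseControl",
]

TRAJECTORY_COLUMNS = [
    "time_s", "x_m", "v_m_s", "a1", "c1", "a2", "c2",
    "u1", "u2", "F1_N", "F2_N", "Fnet_N",
]


@dataclass(frozen=True)
class LoadParams:
    """Mass M (kg), damping b (N·s/m), stiffness k (N/m) of the load."""

    M: float
    b: float
    k: float

    def __post_init__(self) -> None:
        if self.M <= 0 or self.k <= 0 or self.b < 0:
            raise ValueError("require M > 0, k > 0, b >= 0")

    @property
    def omega_n(self) -> float:
        """Undamped natural frequency (rad/s)."""
        return np.sqrt(self.k / self.M)

    @property
    def f_n(self) -> float:
        """Undamped natural frequency (Hz)."""
        return self.omega_n / (2 * np.pi)

    @property
    def zeta(self) -> float:
        """Damping ratio b / (2*sqrt(k*M))."""
        return self.b / (2 * np.sqrt(self.k * self.M))

    @classmethod
    def from_natural(cls, f_n: float, zeta: float, k: float) -> "LoadParams":
        """Construct from natural frequency (Hz), damping ratio and stiffness."""
        omega = 2 * np.pi * f_n
        M = k / omega**2
        b = 2 * zeta * np.sqrt(k * M)
        return cls(M=M, b=b, k=k)

    def to_dict(self) -> dict:
        return {"M": float(self.M), "b": float(self.b), "k": float(self.k)}

    @classmethod
    def from_dict(cls, d: dict) -> "LoadParams":
        if {"f_n", "zeta", "k"} <= set(d):
            return cls.from_natural(float(d["f_n"]), float(d["zeta"]), float(d["k"]))
        return cls(M=float(d["M"]), b=float(d["b"]), k=float(d["k"]))


def default_load_params(f_n: float = 2.0, zeta: float = 0.1, k: float = 1000.0) -> LoadParams:
    """Default load: f_n = 2 Hz, zeta = 0.1, k = 1000 N/m (mid 750–1500)."""
    return LoadParams.from_natural(f_n, zeta, k)


@dataclass(frozen=True)
class SystemState:
    """Full state of the coupled system."""

    x: float = 0.0
    v: float = 0.0
    a1: float = 0.0
    c1: float = 0.0
    a2: float = 0.0
    c2: float = 0.0

    def __post_init__(self) -> None:
        vec = self.as_array()
        if not np.all(np.isfinite(vec)):
            raise ValueError("state must be finite")
        if self.a1 < 0 or self.a2 < 0 or self.c1 < 0 or self.c2 < 0:
            raise ValueError("activation states must be non-negative")

    def as_array(self) -> np.ndarray:
        return np.array([self.x, self.v, self.a1, self.c1, self.a2, self.c2])

    @classmethod
    def from_array(cls, arr: Sequence[float]) -> "SystemState":
        return cls(*[float(z) for z in arr])


class PiecewiseControl:
    """Zero-order-hold control signal defined by (knots, values).

    ``values[i]`` holds on [knots[i], knots[i+1]); the last value holds
    beyond the final knot, and the first before the first knot.  If
    ``period`` is given the signal repeats with that period.
    """

    def __init__(self, knots: Sequence[float], values: Sequence[float],
                 period: float | None = None):
        self.knots = np.asarray(knots, dtype=float)
        self.values = np.asarray(values, dtype=float)
        if self.knots.size != self.values.size or self.knots.size == 0:
            raise ValueError("knots and values must have equal nonzero length")
        if np.any(np.diff(self.knots) <= 0):
            raise ValueError("knots must be strictly increasing")
        self.period = period

    def __call__(self, t):
        t = np.asarray(t, dtype=float)
        if self.period is not None:
            t = np.mod(t - self.knots[0], self.period) + self.knots[0]
        idx = np.clip(np.searchsorted(self.knots, t, side="right") - 1, 0, self.knots.size - 1)
        return self.values[idx]

    def breakpoints(self, t0: float, t1: float) -> np.ndarray:
        """Discontinuity instants inside [t0, t1]."""
        if self.period is None:
            pts = self.knots
        else:
            n0 = int(np.floor((t0 - self.knots[0]) / self.period)) - 1
            n1 = int(np.ceil((t1 - self.knots[0]) / self.period)) + 1
            pts = np.concatenate([self.knots + n * self.period for n in range(n0, n1 + 1)])
        return np.unique(pts[(pts > t0) & (pts < t1)])


def constant_control(value: float) -> PiecewiseControl:
    return PiecewiseControl([0.0], [value])


@dataclass
class Trajectory:
    """Time-gridded states, controls and forces of the coupled system."""

    t: np.ndarray
    states: np.ndarray          # (n, 6): x, v, a1, c1, a2, c2
    u: np.ndarray               # (n, 2)
    F1: np.ndarray
    F2: np.ndarray
    Fnet: np.ndarray
    muscles: tuple[MuscleParams, MuscleParams] | None = None
    load: LoadParams | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if np.any(np.diff(self.t) <= 0):
            raise ValueError("time grid must be strictly increasing")

    @property
    def x(self) -> np.ndarray:
        return self.states[:, 0]

    @property
    def v(self) -> np.ndarray:
        return self.states[:, 1]

    def force_residual(self) -> float:
        """Max relative mismatch between stored forces and the force law."""
        if self.muscles is None:
            raise ValueError("muscle parameters not attached")
        m1, m2 = self.muscles
        import warnings as _w
        with _w.catch_warnings():
            _w.simplefilter("ignore")
            f1, _ = muscle_force(m1, m1.l0 - self.x, np.clip(self.states[:, 2], 0, 1))
            f2, _ = muscle_force(m2, m2.l0 + self.x, np.clip(self.states[:, 4], 0, 1))
        scale = max(np.max(np.abs(self.Fnet)), 1e-12)
        return float(
            max(
                np.max(np.abs(f1 - self.F1)),
                np.max(np.abs(f2 - self.F2)),
                np.max(np.abs((f1 - f2) - self.Fnet)),
            )
            / scale
        )

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            np.column_stack([self.t, self.states, self.u, self.F1, self.F2, self.Fnet]),
            columns=TRAJECTORY_COLUMNS,
        )

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, **kw) -> "Trajectory":
        return cls(
            t=df["time_s"].to_numpy(),
            states=df[["x_m", "v_m_s", "a1", "c1", "a2", "c2"]].to_numpy(),
            u=df[["u1", "u2"]].to_numpy(),
            F1=df["F1_N"].to_numpy(),
            F2=df["F2_N"].to_numpy(),
            Fnet=df["Fnet_N"].to_numpy(),
            **kw,
        )

    @classmethod
    def from_csv(cls, path, **kw) -> "Trajectory":
        return cls.from_dataframe(pd.read_csv(path), **kw)


def coupled_rhs(
    t: float,
    y: np.ndarray,
    muscles: tuple[MuscleParams, MuscleParams],
    load: LoadParams,
    u1: Callable,
    u2: Callable,
) -> np.ndarray:
    """Right-hand side of the six-state coupled ODE."""
    m1, m2 = muscles
    x, v, a1, c1, a2, c2 = y
    l1 = m1.l0 - x
    l2 = m2.l0 + x
    F1 = m1.A + m1.B * l1 + a1 * (m1.C + m1.D * l1)
    F2 = m2.A + m2.B * l2 + a2 * (m2.C + m2.D * l2)
    Fnet = F1 - F2
    return np.array(
        [
            v,
            (Fnet - load.b * v - load.k * x) / load.M,
            (c1 - a1) / m1.tau_a,
            (m1.gain * u1(t) - c1) / m1.tau_c,
            (c2 - a2) / m2.tau_a,
            (m2.gain * u2(t) - c2) / m2.tau_c,
        ]
    )


def passive_equilibrium(
    muscles: tuple[MuscleParams, MuscleParams], load: LoadParams
) -> SystemState:
    """Rest state with zero activation: x balances the passive net force."""
    m1, m2 = muscles
    # A1 + B1(l10 - x) - A2 - B2(l20 + x) = k x
    num = m1.A + m1.B * m1.l0 - m2.A - m2.B * m2.l0
    den = load.k + m1.B + m2.B
    return SystemState(x=num / den)


def simulate_coupled_system(
    muscles: tuple[MuscleParams, MuscleParams],
    load: LoadParams,
    stimulus: tuple[Callable, Callable],
    initial: SystemState,
    horizon: float,
    rtol: float = 1e-8,
    atol: float = 1e-10,
    nodes_per_cycle: int = 200,
    cycle_period: float | None = None,
    blowup_guard: float = 1e3,
) -> Trajectory:
    """Integrate the interconnected muscle–load dynamics.

    ``stimulus`` is a pair of callables u_i(t) (PiecewiseControl instances
    contribute their discontinuities as integration breakpoints).  Adaptive
    integration (RK45, dense output) is resampled onto a uniform grid with
    at least ``nodes_per_cycle`` nodes per oscillation cycle
    (``cycle_period`` defaults to the horizon).

    Raises RuntimeError if any state magnitude exceeds ``blowup_guard``.
    """
    if horizon <= 0:
        raise ValueError("horizon must be positive")
    u1, u2 = stimulus
    breaks = [np.array([])]
    for u in (u1, u2):
        if isinstance(u, PiecewiseControl):
            breaks.append(u.breakpoints(0.0, horizon))
    edges = np.unique(np.concatenate([[0.0, horizon]] + breaks))

    period = cycle_period if cycle_period is not None else horizon
    n_nodes = max(int(np.ceil(nodes_per_cycle * horizon / period)), 2) + 1
    t_grid = np.linspace(0.0, horizon, n_nodes)
    y_grid = np.empty((n_nodes, 6))
    y_grid[0] = initial.as_array()

    y = initial.as_array()
    filled = 1
    for lo, hi in zip(edges[:-1], edges[1:]):
        t_eval = t_grid[(t_grid > lo) & (t_grid <= hi)]
        sol = solve_ivp(
            coupled_rhs,
            (lo, hi),
            y,
            args=(muscles, load, u1, u2),
            method="RK45",
            rtol=rtol,
            atol=atol,
            dense_output=True,
        )
        if not sol.success:
            raise RuntimeError(f"integration failed on [{lo}, {hi}]: {sol.message}")
        if np.max(np.abs(sol.y)) > blowup_guard:
            raise RuntimeError("state blow-up beyond guard; check parameters")
        if t_eval.size:
            y_grid[filled : filled + t_eval.size] = sol.sol(t_eval).T
            filled += t_eval.size
        y = sol.y[:, -1]
    assert filled == n_nodes

    uu = np.column_stack([np.asarray(u1(t_grid), dtype=float).reshape(-1) * np.ones(n_nodes),
                          np.asarray(u2(t_grid), dtype=float).reshape(-1) * np.ones(n_nodes)])
    m1, m2 = muscles
    x = y_grid[:, 0]
    F1 = m1.A + m1.B * (m1.l0 - x) + y_grid[:, 2] * (m1.C + m1.D * (m1.l0 - x))
    F2 = m2.A + m2.B * (m2.l0 + x) + y_grid[:, 4] * (m2.C + m2.D * (m2.l0 + x))
    return Trajectory(
        t=t_grid,
        states=y_grid,
        u=uu,
        F1=F1,
        F2=F2,
        Fnet=F1 - F2,
        muscles=muscles,
        load=load,
        meta={"rtol": rtol, "atol": atol},
    )


def load_impedance(load: LoadParams, omega: float | np.ndarray) -> np.ndarray:
    """Mechanical impedance Z_L(j*omega) = b + j*(M*omega - k/omega) (N·s/m).

    The impedance relates force to velocity, Z = F/V; its real part is the
    damping b at every frequency and its reactance vanishes at omega_n.
    """
    omega = np.asarray(omega, dtype=float)
    if np.any(omega <= 0):
        raise ValueError("omega must be positive (pole at zero)")
    return load.b + 1j * (load.M * omega - load.k / omega)


def steady_state_periodic_response(
    load: LoadParams,
    forcing: dict[int, complex] | Sequence[complex],
    omega: float,
) -> dict:
    """Exact periodic response of the linear load to band-limited forcing.

    ``forcing`` maps harmonic index h (of the base frequency ``omega``) to
    a complex amplitude F_h, with F(t) = Re(sum_h F_h exp(j h omega t)).
    Returns per-harmonic velocity and displacement coefficients and the
    mean power delivered, sum_h 0.5*Re(F_h * conj(V_h)), which equals the
    damper dissipation b*<v^2>.
    """
    if omega <= 0:
        raise ValueError("omega must be positive")
    if not isinstance(forcing, dict):
        forcing = {h: f for h, f in enumerate(forcing)}
    vel: dict[int, complex] = {}
    disp: dict[int, complex] = {}
    power = 0.0
    for h, Fh in forcing.items():
        if h < 0:
            raise ValueError("harmonic indices must be >= 0")
        if h == 0:
            disp[0] = complex(np.real(Fh)) / load.k
            vel[0] = 0.0
            continue
        if load.b == 0 and abs(h * omega - load.omega_n) < 1e-9 * load.omega_n:
            raise ValueError("undamped resonance: harmonic at omega_n with b = 0")
        Z = load.b + 1j * (load.M * h * omega - load.k / (h * omega))
        Vh = Fh / Z
        vel[h] = Vh
        disp[h] = Vh / (1j * h * omega)
        power += 0.5 * np.real(Fh * np.conj(Vh))
    return {"velocity": vel, "displacement": disp, "mean_power_W": float(power)}
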