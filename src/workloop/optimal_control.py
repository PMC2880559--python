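"""Power-optimal cyclic control of the muscle–load system.

The cyclic work ∮ F_net dx delivered to the load over one period T = 1/f is
maximized over the bounded stimulation inputs u1, u2.  With running cost
L = -F_net*v (negative instantaneous power) the Hamiltonian

    H = -F_net*v + lambda' * f(state, u)

is linear in the controls, so Pontryagin's minimum principle yields a
bang-bang law: each u_i sits at a bound according to the sign of its
switching function, the costate conjugate to that muscle's stimulated
calcium state scaled by the input gain.  States and costates must satisfy
cyclic boundary conditions over the period.

Discontinuous controls defeat generic collocation, so the solver replaces
the bang-bang law by a steep sigmoid of the switching function and
continues the sharpness parameter beta upward (homotopy) until the controls
are numerically saturated; each stage is a smooth cyclic two-point BVP
solved by collocation on normalized time.  Cyclic orbits of an autonomous
system are degenerate under time shift, so the BVP is augmented with a
scalar unfolding parameter on the velocity equation and a phase anchor
v(0) = 0; the parameter returns to ~0 at a true orbit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.integrate import solve_bvp, solve_ivp
from scipy.optimize import minimize
from scipy.special import expit

from .load_dynamics import (
    LoadParams,
    PiecewiseControl,
    SystemState,
    Trajectory,
    passive_equilibrium,
    simulate_coupled_system,
)
from .muscle_model import MuscleParams

__all__ = [
    "OptimalControlProblem",
    "OptimalSolution",
    "hamiltonian_and_costate_rhs",
    "bang_bang_control",
    "solve_cyclic_optimal_control",
    "sweep_optimal_power",
    "impedance_free_optimal_power",
    "impedance_free_power_sweep",
    "impedance_free_synergy",
    "direct_transcription_work",
    "burst_control",
]

DEFAULT_BETA_SCHEDULE = (10.0, 40.0, 160.0, 640.0, 2560.0, 10240.0)


@dataclass(frozen=True)
class OptimalControlProblem:
    """One cyclic power-optimization instance.

    The single-muscle case is expressed by zeroing the antagonist's force
    coefficients (``MuscleParams.zeroed()``); such a muscle is held at
    u_min and excluded from the switching logic.
    """

    muscles: tuple[MuscleParams, MuscleParams]
    load: LoadParams
    frequency: float

    def __post_init__(self) -> None:
        if self.frequency <= 0:
            raise ValueError("frequency must be positive")
        for m in self.muscles:
            if not np.isfinite([m.u_min, m.u_max]).all():
                raise ValueError("control bounds must be finite (unbounded "
                                 "controls make the problem ill-posed)")

    @property
    def T(self) -> float:
        return 1.0 / self.frequency

    @property
    def active(self) -> tuple[bool, bool]:
        return tuple(bool(m.C != 0 or m.D != 0) for m in self.muscles)


@dataclass
class OptimalSolution:
    """Converged (or best-iterate) cyclic optimum with diagnostics."""

    trajectory: Trajectory
    costates: np.ndarray            # (n, 6)
    switching: np.ndarray           # (n, 2)
    hamiltonian: np.ndarray         # (n,)
    cyclic_work_J: float
    mean_power_W: float
    converged: bool
    trivial: bool
    bc_residual: float
    rms_residual: float
    unfolding_parameter: float
    beta_final: float
    hamiltonian_variation: float
    interior_fraction: float
    possibly_singular: bool
    frequency: float
    meta: dict = field(default_factory=dict)

    def mean_power_per_kg(self, muscle_mass_kg: float) -> float:
        return self.mean_power_W / muscle_mass_kg


# ---------------------------------------------------------------------------
# model derivatives shared by dynamics, Hamiltonian and Jacobians
# ---------------------------------------------------------------------------


def _force_terms(problem, x, a1, a2):
    """F_net, muscle stiffness Km, and activation gradients G1, G2 of F_net."""
    m1, m2 = problem.muscles
    l1 = m1.l0 - x
    l2 = m2.l0 + x
    F1 = m1.A + m1.B * l1 + a1 * (m1.C + m1.D * l1)
    F2 = m2.A + m2.B * l2 + a2 * (m2.C + m2.D * l2)
    Km = (m1.B + m1.D * a1) + (m2.B + m2.D * a2)
    G1 = m1.C + m1.D * l1
    G2 = -(m2.C + m2.D * l2)
    return F1 - F2, Km, G1, G2, F1, F2


def state_rhs(problem: OptimalControlProblem, y, u1, u2):
    """Six-state dynamics f(state, u) (vectorized over trailing axis)."""
    m1, m2 = problem.muscles
    load = problem.load
    x, v, a1, c1, a2, c2 = y[:6]
    Fnet, _, _, _, _, _ = _force_terms(problem, x, a1, a2)
    return np.stack(
        [
            v,
            (Fnet - load.b * v - load.k * x) / load.M,
            (c1 - a1) / m1.tau_a,
            (m1.gain * u1 - c1) / m1.tau_c,
            (c2 - a2) / m2.tau_a,
            (m2.gain * u2 - c2) / m2.tau_c,
        ]
    )


def hamiltonian_and_costate_rhs(problem: OptimalControlProblem, state, costate, controls):
    """Hamiltonian value and costate derivative -dH/dstate.

    ``state`` and ``costate`` are 6-vectors (or (6, n) arrays); ``controls``
    the pair (u1, u2).  The bilinear force model enters both through the
    running cost -F_net*v and through the load acceleration.
    """
    state = np.asarray(state, dtype=float)
    costate = np.asarray(costate, dtype=float)
    if not (np.all(np.isfinite(state)) and np.all(np.isfinite(costate))):
        raise ValueError("non-finite state or costate")
    m1, m2 = problem.muscles
    load = problem.load
    x, v, a1, c1, a2, c2 = state[:6]
    lx, lv, la1, lc1, la2, lc2 = costate[:6]
    u1, u2 = controls
    Fnet, Km, G1, G2, _, _ = _force_terms(problem, x, a1, a2)

    f = state_rhs(problem, state, u1, u2)
    H = -Fnet * v + (costate * f).sum(axis=0)

    lam_dot = np.stack(
        [
            -Km * v + lv * (Km + load.k) / load.M,
            Fnet - lx + lv * load.b / load.M,
            G1 * (v - lv / load.M) + la1 / m1.tau_a,
            -la1 / m1.tau_a + lc1 / m1.tau_c,
            G2 * (v - lv / load.M) + la2 / m2.tau_a,
            -la2 / m2.tau_a + lc2 / m2.tau_c,
        ]
    )
    return H, lam_dot


def switching_functions(problem: OptimalControlProblem, costate):
    """sigma_i = gain_i * lambda_ci / tau_ci; u_i = u_max where sigma_i < 0."""
    m1, m2 = problem.muscles
    costate = np.asarray(costate, dtype=float)
    s1 = m1.gain * costate[3] / m1.tau_c
    s2 = m2.gain * costate[5] / m2.tau_c
    act = problem.active
    if not act[0]:
        s1 = np.zeros_like(s1)
    if not act[1]:
        s2 = np.zeros_like(s2)
    return np.stack([s1, s2])


def bang_bang_control(problem: OptimalControlProblem, costate):
    """Pointwise Hamiltonian-minimizing controls; ties broken to u_min."""
    sig = switching_functions(problem, costate)
    out = []
    for i, m in enumerate(problem.muscles):
        u = np.where(sig[i] < 0, m.u_max, m.u_min)
        out.append(u if u.ndim else float(u))
    return tuple(out)


def _smoothed_controls(problem, costate, beta_over_s):
    """Sigmoid relaxation of the bang-bang law (homotopy stage law)."""
    sig = switching_functions(problem, costate)
    us = []
    for i, m in enumerate(problem.muscles):
        if problem.active[i]:
            us.append(m.u_min + (m.u_max - m.u_min) * expit(-beta_over_s * sig[i]))
        else:
            us.append(np.full_like(np.asarray(sig[i], dtype=float), m.u_min))
    return us[0], us[1]


# ---------------------------------------------------------------------------
# the cyclic BVP on normalized time
# ---------------------------------------------------------------------------


def _bvp_funcs(problem: OptimalControlProblem, beta_over_s: float):
    """Collocation functions for one homotopy stage on normalized time.

    The sigmoid control law is the argmin of the Hamiltonian plus an
    entropy penalty, so the smoothed closed-loop field conserves that
    regularized Hamiltonian exactly; cyclic orbits therefore carry the
    degeneracies of a conservative system (phase shift + a unit Floquet
    pair).  The BVP is regularized the standard way: an unfolding
    parameter p adds artificial damping along the Hamiltonian gradient
    grad H = (-lambda_dot, f) — any periodic orbit then forces p = 0 — and
    the phase is anchored by v(0) = 0.
    """
    m1, m2 = problem.muscles
    load = problem.load
    T = problem.T
    act1, act2 = problem.active
    du_fac1 = (m1.gain / m1.tau_c) ** 2 * (m1.u_max - m1.u_min) * beta_over_s if act1 else 0.0
    du_fac2 = (m2.gain / m2.tau_c) ** 2 * (m2.u_max - m2.u_min) * beta_over_s if act2 else 0.0

    def fun(tau, y, p):
        state, costate = y[:6], y[6:]
        u1, u2 = _smoothed_controls(problem, costate, beta_over_s)
        f = state_rhs(problem, state, u1, u2)
        _, lam_dot = hamiltonian_and_costate_rhs(problem, state, costate, (u1, u2))
        F = np.vstack([f, lam_dot])
        G = np.vstack([-F[6:], F[:6]])  # grad of the regularized Hamiltonian
        return T * (F + p[0] * G)

    def jac(tau, y, p):
        m = y.shape[1]
        x, v, a1, c1, a2, c2 = y[:6]
        lx, lv, la1, lc1, la2, lc2 = y[6:]
        _, Km, G1, G2, _, _ = _force_terms(problem, x, a1, a2)
        J = np.zeros((12, 12, m))
        # state rows
        J[0, 1] = 1.0
        J[1, 0] = (-Km - load.k) / load.M
        J[1, 1] = -load.b / load.M
        J[1, 2] = G1 / load.M
        J[1, 4] = G2 / load.M
        J[2, 2] = -1.0 / m1.tau_a
        J[2, 3] = 1.0 / m1.tau_a
        J[3, 3] = -1.0 / m1.tau_c
        J[4, 4] = -1.0 / m2.tau_a
        J[4, 5] = 1.0 / m2.tau_a
        J[5, 5] = -1.0 / m2.tau_c
        if act1:
            z1 = -beta_over_s * m1.gain * lc1 / m1.tau_c
            e1 = expit(z1)
            J[3, 9] = -du_fac1 * e1 * (1.0 - e1)
        if act2:
            z2 = -beta_over_s * m2.gain * lc2 / m2.tau_c
            e2 = expit(z2)
            J[5, 11] = -du_fac2 * e2 * (1.0 - e2)
        # costate rows
        vml = v - lv / load.M
        J[6, 1] = -Km
        J[6, 2] = (m1.D) * (lv / load.M - v)
        J[6, 4] = (m2.D) * (lv / load.M - v)
        J[6, 7] = (Km + load.k) / load.M
        J[7, 0] = -Km
        J[7, 2] = G1
        J[7, 4] = G2
        J[7, 6] = -1.0
        J[7, 7] = load.b / load.M
        J[8, 0] = -m1.D * vml
        J[8, 1] = G1
        J[8, 7] = -G1 / load.M
        J[8, 8] = 1.0 / m1.tau_a
        J[9, 8] = -1.0 / m1.tau_a
        J[9, 9] = 1.0 / m1.tau_c
        J[10, 0] = -m2.D * vml
        J[10, 1] = G2
        J[10, 7] = -G2 / load.M
        J[10, 10] = 1.0 / m2.tau_a
        J[11, 10] = -1.0 / m2.tau_a
        J[11, 11] = 1.0 / m2.tau_c

        JG = np.concatenate([-J[6:], J[:6]], axis=0)
        state, costate = y[:6], y[6:]
        u1, u2 = _smoothed_controls(problem, costate, beta_over_s)
        f = state_rhs(problem, state, u1, u2)
        _, lam_dot = hamiltonian_and_costate_rhs(problem, state, costate, (u1, u2))
        G = np.vstack([-lam_dot, f])
        dfdp = T * G[:, None, :]
        return T * (J + p[0] * JG), dfdp

    def bc(ya, yb, p):
        return np.concatenate([ya - yb, [ya[1]]])

    def bc_jac(ya, yb, p):
        dya = np.vstack([np.eye(12), np.zeros((1, 12))])
        dya[12, 1] = 1.0
        dyb = np.vstack([-np.eye(12), np.zeros((1, 12))])
        dp = np.zeros((13, 1))
        return dya, dyb, dp

    return fun, jac, bc, bc_jac


# ---------------------------------------------------------------------------
# initial guess: burst forward simulation + periodic adjoint solve
# ---------------------------------------------------------------------------


def burst_control(frequency: float, phase: float, duty: float,
                  u_max: float = 1.0, u_min: float = 0.0) -> PiecewiseControl:
    """Periodic rectangular burst: on during [phase, phase+duty) (cycle fractions)."""
    T = 1.0 / frequency
    phase = phase % 1.0
    end = phase + duty
    if end <= 1.0:
        knots = [0.0, phase * T, end * T]
        vals = [u_min, u_max, u_min]
        if phase == 0.0:
            knots, vals = [0.0, end * T], [u_max, u_min]
    else:
        knots = [0.0, (end - 1.0) * T, phase * T]
        vals = [u_max, u_min, u_max]
    return PiecewiseControl(knots, vals, period=T)


def _simulate_bursts(problem, phase, duty, n_cycles, rtol=1e-7, atol=1e-9,
                     nodes_per_cycle=200):
    f = problem.frequency
    m1, m2 = problem.muscles
    u1 = burst_control(f, phase, duty, m1.u_max, m1.u_min)
    if problem.active[1]:
        u2 = burst_control(f, phase + 0.5, duty, m2.u_max, m2.u_min)
    else:
        u2 = PiecewiseControl([0.0], [m2.u_min])
    init = passive_equilibrium(problem.muscles, problem.load)
    return simulate_coupled_system(
        problem.muscles, problem.load, (u1, u2), init,
        horizon=n_cycles / f, rtol=rtol, atol=atol,
        nodes_per_cycle=nodes_per_cycle, cycle_period=1.0 / f,
    )


def _last_cycle_work(traj: Trajectory, frequency: float) -> float:
    T = 1.0 / frequency
    mask = traj.t >= traj.t[-1] - T - 1e-12
    return float(np.trapezoid(traj.Fnet[mask] * traj.v[mask], traj.t[mask]))


def _periodic_adjoint(problem, t_cycle, y_cycle):
    """Periodic solution of the linear adjoint ODE along a frozen cycle."""
    T = problem.T
    m1, m2 = problem.muscles
    load = problem.load

    def interp(t):
        tt = np.mod(t, T)
        return np.array([np.interp(tt, t_cycle, y_cycle[:, i]) for i in range(6)])

    def rhs(t, Y):
        Y = Y.reshape(6, 7)
        s = interp(t)
        x, v, a1, c1, a2, c2 = s
        Fnet, Km, G1, G2, _, _ = _force_terms(problem, x, a1, a2)
        A = np.zeros((6, 6))
        A[0, 1] = 1.0
        A[1, 0] = (-Km - load.k) / load.M
        A[1, 1] = -load.b / load.M
        A[1, 2] = G1 / load.M
        A[1, 4] = G2 / load.M
        A[2, 2] = -1.0 / m1.tau_a
        A[2, 3] = 1.0 / m1.tau_a
        A[3, 3] = -1.0 / m1.tau_c
        A[4, 4] = -1.0 / m2.tau_a
        A[4, 5] = 1.0 / m2.tau_a
        A[5, 5] = -1.0 / m2.tau_c
        gradL = np.array([Km * v, -Fnet, -G1 * v, 0.0, -G2 * v, 0.0])
        dY = -A.T @ Y
        dY[:, 6] -= gradL
        return dY.reshape(-1)

    Y0 = np.hstack([np.eye(6), np.zeros((6, 1))]).reshape(-1)
    sol = solve_ivp(rhs, (0.0, T), Y0, method="RK45", rtol=1e-8, atol=1e-10,
                    dense_output=True)
    if not sol.success:
        raise RuntimeError("adjoint integration failed")
    YT = sol.y[:, -1].reshape(6, 7)
    Phi, psi = YT[:, :6], YT[:, 6]
    lam0 = np.linalg.solve(np.eye(6) - Phi, psi)

    lam = np.empty((t_cycle.size, 6))
    for j, t in enumerate(t_cycle):
        Yt = sol.sol(t).reshape(6, 7)
        lam[j] = Yt[:, :6] @ lam0 + Yt[:, 6]
    return lam


def _roll_cycle(t, Y, lam):
    """Shift the cycle start to a node with v ~ 0 and x > 0 (phase anchor)."""
    x, v = Y[:, 0], Y[:, 1]
    n = len(t) - 1  # last node duplicates the first in time+T
    xs, vs = x[:n], v[:n]
    cand = [i for i in range(n) if vs[i] * vs[(i + 1) % n] <= 0 and xs[i] > 0]
    i0 = cand[0] if cand else int(np.argmax(xs))
    idx = (np.arange(n) + i0) % n
    Yr = np.vstack([Y[idx], Y[idx[:1]]])
    lamr = np.vstack([lam[idx], lam[idx[:1]]])
    return Yr, lamr


def _initial_guess(problem, duty=0.4, n_phases=8, settle_cycles=8, n_mesh=121):
    """Phase-scanned burst simulation + periodic adjoint -> full 12-state guess."""
    phases = np.arange(n_phases) / n_phases
    works = []
    for ph in phases:
        try:
            traj = _simulate_bursts(problem, ph, duty, 4, rtol=1e-6, atol=1e-8,
                                    nodes_per_cycle=120)
            works.append(_last_cycle_work(traj, problem.frequency))
        except RuntimeError:
            works.append(-np.inf)
    order = np.argsort(works)[::-1]
    guesses = []
    for ph in phases[order[:2]]:
        traj = _simulate_bursts(problem, ph, duty, settle_cycles)
        T = problem.T
        mask = traj.t >= traj.t[-1] - T - 1e-12
        t_cycle = traj.t[mask] - traj.t[mask][0]
        y_cycle = traj.states[mask]
        lam = _periodic_adjoint(problem, t_cycle, y_cycle)
        y_cycle, lam = _roll_cycle(t_cycle, y_cycle, lam)
        tau = np.linspace(0.0, 1.0, n_mesh)
        src = t_cycle / t_cycle[-1]
        Y = np.vstack([
            np.array([np.interp(tau, src, y_cycle[:, i]) for i in range(6)]),
            np.array([np.interp(tau, src, lam[:, i]) for i in range(6)]),
        ])
        guesses.append((tau, Y))
    return guesses


def _sigma_scale(problem, Y) -> float:
    sig = switching_functions(problem, Y[6:])
    act = np.array(problem.active)
    rms = [np.sqrt(np.mean(sig[i] ** 2)) for i in range(2) if act[i]]
    s = max(rms) if rms else 1.0
    return float(max(s, 1e-12))


def _package_solution(problem, sol, beta, s, nodes_per_cycle=400) -> OptimalSolution:
    T = problem.T
    tau = np.linspace(0.0, 1.0, nodes_per_cycle + 1)
    Y = sol.sol(tau)
    state, costate = Y[:6], Y[6:]
    u1, u2 = _smoothed_controls(problem, costate, beta / s)
    sig = switching_functions(problem, costate)
    H, _ = hamiltonian_and_costate_rhs(problem, state, costate, (u1, u2))

    m1, m2 = problem.muscles
    x = state[0]
    F1 = m1.A + m1.B * (m1.l0 - x) + state[2] * (m1.C + m1.D * (m1.l0 - x))
    F2 = m2.A + m2.B * (m2.l0 + x) + state[4] * (m2.C + m2.D * (m2.l0 + x))
    traj = Trajectory(
        t=tau * T, states=state.T.copy(), u=np.column_stack([u1, u2]),
        F1=F1, F2=F2, Fnet=F1 - F2, muscles=problem.muscles, load=problem.load,
    )
    J = float(np.trapezoid(traj.Fnet * traj.v, traj.t))
    bc_res = float(np.max(np.abs(np.concatenate(
        [Y[:, 0] - Y[:, -1], [Y[1, 0]]]))))
    x_amp = float(np.ptp(x))
    trivial = x_amp < 1e-6 or abs(J) < 1e-9

    interior = 0.0
    singular = False
    n_active = 0
    for i, (m, act) in enumerate(zip(problem.muscles, problem.active)):
        if not act:
            continue
        n_active += 1
        u = (u1, u2)[i]
        du = m.u_max - m.u_min
        interior = max(interior, float(np.mean(
            (u > m.u_min + 1e-3 * du) & (u < m.u_max - 1e-3 * du))))
        singular = singular or bool(np.mean(np.abs(sig[i]) < 1e-6 * s) > 0.05)

    scaleH = max(float(np.mean(np.abs(H))), abs(J) / T, 1e-12)
    h_var = float(np.ptp(H)) / scaleH
    converged = bool(sol.status == 0) and not trivial
    lo1, hi1 = m1.operating_range
    within_range = bool(
        (m1.l0 - x.max()) >= lo1 - 1e-12 and (m1.l0 - x.min()) <= hi1 + 1e-12
        and (m2.l0 + x.min()) >= m2.operating_range[0] - 1e-12
        and (m2.l0 + x.max()) <= m2.operating_range[1] + 1e-12
    )
    return OptimalSolution(
        trajectory=traj,
        costates=costate.T.copy(),
        switching=sig.T.copy(),
        hamiltonian=H,
        cyclic_work_J=J,
        mean_power_W=J * problem.frequency,
        converged=converged,
        trivial=trivial,
        bc_residual=bc_res,
        rms_residual=float(np.max(sol.rms_residuals)),
        unfolding_parameter=float(sol.p[0]),
        beta_final=beta,
        hamiltonian_variation=h_var,
        interior_fraction=interior,
        possibly_singular=singular,
        frequency=problem.frequency,
        meta={"sigma_scale": s, "status": int(sol.status), "n_mesh": sol.x.size,
              "within_operating_range": within_range},
    )


def solve_cyclic_optimal_control(
    problem: OptimalControlProblem,
    init: OptimalSolution | tuple[np.ndarray, np.ndarray] | None = None,
    beta_schedule=DEFAULT_BETA_SCHEDULE,
    tol: float = 1e-4,
    max_nodes: int = 8000,
) -> OptimalSolution:
    """Solve the cyclic power-optimal control problem by homotopy collocation.

    ``init`` may be a previous :class:`OptimalSolution` (warm start, e.g.
    frequency continuation: the final-sharpness stage is attempted
    directly, backing off through the schedule on failure) or a ``(tau,
    Y)`` mesh/values pair.  Without a warm start the guess is built by
    phase-scanned burst forward simulation plus a periodic adjoint solve,
    and the full beta schedule is run.

    Returns the best iterate flagged ``converged=False`` if the final stage
    fails; a zero-motion solution is flagged ``trivial``.
    """
    attempts: list[tuple[np.ndarray, np.ndarray, float, tuple]] = []
    if isinstance(init, OptimalSolution):
        tau = init.trajectory.t / init.trajectory.t[-1]
        Y = np.hstack([init.trajectory.states, init.costates]).T
        s = init.meta.get("sigma_scale", _sigma_scale(problem, Y))
        attempts.append((tau, Y, s, (beta_schedule[-1],)))
        attempts.append((tau, Y, s, tuple(beta_schedule[len(beta_schedule) // 2:])))
    elif init is not None:
        tau, Y = init
        attempts.append((tau, Y, _sigma_scale(problem, Y), tuple(beta_schedule)))

    best = None
    for tau, Y, s, schedule in attempts:
        solu = _run_homotopy(problem, tau, Y, s, schedule, tol, max_nodes)
        if solu is not None and solu.converged:
            return solu
        if solu is not None and (best is None or solu.cyclic_work_J > best.cyclic_work_J):
            best = solu

    for tau, Y in _initial_guess(problem):
        s = _sigma_scale(problem, Y)
        solu = _run_homotopy(problem, tau, Y, s, tuple(beta_schedule), tol, max_nodes)
        if solu is not None and solu.converged:
            return solu
        if solu is not None and (best is None or solu.cyclic_work_J > best.cyclic_work_J):
            best = solu
    if best is None:
        raise RuntimeError("cyclic BVP solver produced no iterate")
    return best


def _run_homotopy(problem, tau, Y, s, schedule, tol, max_nodes):
    sol_obj = None
    for i, beta in enumerate(schedule):
        fun, jac, bc, bc_jac = _bvp_funcs(problem, beta / s)
        p0 = np.array([sol_obj.p[0] if sol_obj is not None else 0.0])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = solve_bvp(fun, bc, tau, Y, p=p0, fun_jac=jac, bc_jac=bc_jac,
                            tol=tol, max_nodes=max_nodes, verbose=0)
        if res.status != 0 and sol_obj is None:
            return None
        if res.status != 0:
            # keep the last successful (smoother) stage as the best iterate
            return _package_solution(problem, sol_obj, schedule[i - 1], s)
        sol_obj = res
        tau = res.x
        Y = res.y
    # final polish at a tighter tolerance; keep the looser solve if it fails
    fun, jac, bc, bc_jac = _bvp_funcs(problem, schedule[-1] / s)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = solve_bvp(fun, bc, tau, Y, p=sol_obj.p.copy(), fun_jac=jac,
                        bc_jac=bc_jac, tol=tol / 10, max_nodes=2 * max_nodes,
                        verbose=0)
    if res.status == 0:
        sol_obj = res
    return _package_solution(problem, sol_obj, schedule[-1], s)


# ---------------------------------------------------------------------------
# frequency sweeps
# ---------------------------------------------------------------------------


def sweep_optimal_power(
    muscles: tuple[MuscleParams, MuscleParams],
    load: LoadParams,
    frequencies,
    beta_schedule=DEFAULT_BETA_SCHEDULE,
    tol: float = 1e-6,
) -> dict:
    """Solve the cyclic optimum across a frequency grid with continuation.

    Solving starts at the grid point nearest the load natural frequency
    (where convergence is easiest) and continues outward in both
    directions, warm-starting each solve from its converged neighbor.
    Returns the per-frequency table, the solutions, and the power-optimal
    frequency f* over converged points; the sweep is flagged if more than
    half the points fail.
    """
    freqs = np.asarray(frequencies, dtype=float)
    if freqs.size < 2:
        raise ValueError("need at least two frequencies")
    order = np.argsort(np.abs(freqs - load.f_n))
    i_start = int(order[0])
    seq = list(range(i_start, len(freqs))) + list(range(i_start - 1, -1, -1))

    solutions: dict[int, OptimalSolution] = {}
    warm_up = None
    warm_down = None
    for idx in seq:
        warm = warm_up if idx >= i_start else warm_down
        problem = OptimalControlProblem(muscles=muscles, load=load, frequency=freqs[idx])
        try:
            solu = solve_cyclic_optimal_control(problem, init=warm,
                                                beta_schedule=beta_schedule, tol=tol)
        except RuntimeError:
            solu = None
        solutions[idx] = solu
        if solu is not None and solu.converged:
            if idx >= i_start:
                warm_up = solu
                if idx == i_start:
                    warm_down = solu
            else:
                warm_down = solu

    rows = []
    for i, f in enumerate(freqs):
        solu = solutions[i]
        rows.append({
            "frequency_Hz": float(f),
            "mean_power_W": solu.mean_power_W if solu is not None else np.nan,
            "cyclic_work_J": solu.cyclic_work_J if solu is not None else np.nan,
            "converged": bool(solu.converged) if solu is not None else False,
        })
    conv = [r for r in rows if r["converged"]]
    flagged = len(conv) < 0.5 * len(rows)
    f_star = max(conv, key=lambda r: r["mean_power_W"])["frequency_Hz"] if conv else np.nan
    return {
        "table": rows,
        "solutions": [solutions[i] for i in range(len(freqs))],
        "f_star_Hz": f_star,
        "flagged": flagged,
        "n_converged": len(conv),
    }


# ---------------------------------------------------------------------------
# impedance-free benchmark
# ---------------------------------------------------------------------------


def impedance_free_optimal_power(
    load: LoadParams, F_max: float, frequency: float, n_harmonics: int = 99
) -> dict:
    """Optimal mean power of a bounded impedance-free force source.

    For a linear load the power-optimal periodic forcing under |F| <= F_max
    is the symmetric square wave of amplitude F_max phase-locked to the
    velocity sign; its mean power follows from the Fourier steady state,
    P = sum_{h odd} 0.5 |F_h|^2 b / |Z(j h w)|^2 with F_h = 4 F_max/(pi h).
    """
    if F_max < 0:
        raise ValueError("F_max must be >= 0")
    if load.b <= 0:
        raise ValueError("b = 0 gives unbounded power at resonance")
    if frequency <= 0:
        raise ValueError("frequency must be positive")
    omega = 2 * np.pi * frequency
    h = np.arange(1, n_harmonics + 1, 2)
    Fh = 4.0 * F_max / (np.pi * h)
    Z = load.b + 1j * (load.M * h * omega - load.k / (h * omega))
    power = float(np.sum(0.5 * Fh**2 * load.b / np.abs(Z) ** 2))
    return {
        "mean_power_W": power,
        "forcing": "square wave, amplitude F_max, in phase with velocity",
        "F_max": float(F_max),
        "frequency_Hz": float(frequency),
    }


def impedance_free_power_sweep(load: LoadParams, F_max: float, frequencies) -> dict:
    """Power of the bounded force source across a grid; optimum sits at f_n."""
    freqs = np.asarray(frequencies, dtype=float)
    powers = np.array([
        impedance_free_optimal_power(load, F_max, f)["mean_power_W"] for f in freqs
    ])
    return {
        "frequencies_Hz": freqs,
        "mean_power_W": powers,
        "f_star_Hz": float(freqs[np.argmax(powers)]),
    }


def impedance_free_synergy(
    load: LoadParams, F1_max: float, F2_max: float, frequency: float
) -> dict:
    """Synergy ratio of two bounded impedance-free actuators on one load.

    Acting together their force bounds add, so W12 is the optimal work at
    bound F1+F2 and S = (F1+F2)^2/(F1^2+F2^2): exactly 2 for equal bounds
    at every frequency, in (1, 2] otherwise.
    """
    P1 = impedance_free_optimal_power(load, F1_max, frequency)["mean_power_W"]
    P2 = impedance_free_optimal_power(load, F2_max, frequency)["mean_power_W"]
    P12 = impedance_free_optimal_power(load, F1_max + F2_max, frequency)["mean_power_W"]
    return {"W1": P1, "W2": P2, "W12": P12, "S": P12 / (P1 + P2)}


# ---------------------------------------------------------------------------
# direct transcription oracle
# ---------------------------------------------------------------------------


def direct_transcription_work(
    problem: OptimalControlProblem,
    n_intervals: int = 20,
    n_cycles: int = 8,
    steps_per_interval: int = 20,
    maxiter: int = 120,
    u0: np.ndarray | None = None,
) -> dict:
    """Independent check of the BVP optimum by dense control transcription.

    Controls are piecewise constant on ``n_intervals`` per cycle (repeated
    every cycle), the system is integrated from the passive equilibrium for
    ``n_cycles`` with fixed-step RK4, and the work of the final cycle is
    maximized with L-BFGS-B under the bound constraints.  Entirely
    independent of the costate/collocation machinery.
    """
    m1, m2 = problem.muscles
    load = problem.load
    act1, act2 = problem.active
    T = problem.T
    n_steps = n_intervals * steps_per_interval
    dt = T / n_steps
    y0 = passive_equilibrium(problem.muscles, problem.load).as_array()

    A1, B1, C1, D1, l10 = m1.A, m1.B, m1.C, m1.D, m1.l0
    A2, B2, C2, D2, l20 = m2.A, m2.B, m2.C, m2.D, m2.l0
    M, b, k = load.M, load.b, load.k
    g1, tc1, ta1 = m1.gain, m1.tau_c, m1.tau_a
    g2, tc2, ta2 = m2.gain, m2.tau_c, m2.tau_a

    def rhs(y, u1, u2):
        x, v, a1, c1, a2, c2 = y
        F1 = A1 + B1 * (l10 - x) + a1 * (C1 + D1 * (l10 - x))
        F2 = A2 + B2 * (l20 + x) + a2 * (C2 + D2 * (l20 + x))
        return (
            v,
            (F1 - F2 - b * v - k * x) / M,
            (c1 - a1) / ta1,
            (g1 * u1 - c1) / tc1,
            (c2 - a2) / ta2,
            (g2 * u2 - c2) / tc2,
        )

    def simulate(u_flat):
        u1s = u_flat[:n_intervals] if act1 else np.full(n_intervals, m1.u_min)
        u2s = (u_flat[n_intervals:] if act1 else u_flat)[:n_intervals] \
            if act2 else np.full(n_intervals, m2.u_min)
        y = tuple(y0)
        work = 0.0
        for cyc in range(n_cycles):
            last = cyc == n_cycles - 1
            for i in range(n_intervals):
                u1, u2 = u1s[i], u2s[i]
                for _ in range(steps_per_interval):
                    k1 = rhs(y, u1, u2)
                    y2 = tuple(y[j] + 0.5 * dt * k1[j] for j in range(6))
                    k2 = rhs(y2, u1, u2)
                    y3 = tuple(y[j] + 0.5 * dt * k2[j] for j in range(6))
                    k3 = rhs(y3, u1, u2)
                    y4 = tuple(y[j] + dt * k3[j] for j in range(6))
                    k4 = rhs(y4, u1, u2)
                    if last:
                        # accumulate ∮ F_net dx with the same RK4 quadrature
                        x, v = y[0], y[1]
                        F1 = A1 + B1 * (l10 - x) + y[2] * (C1 + D1 * (l10 - x))
                        F2 = A2 + B2 * (l20 + x) + y[4] * (C2 + D2 * (l20 + x))
                        p1 = (F1 - F2) * v
                        x4, v4 = y4[0], y4[1]
                        F14 = A1 + B1 * (l10 - x4) + y4[2] * (C1 + D1 * (l10 - x4))
                        F24 = A2 + B2 * (l20 + x4) + y4[4] * (C2 + D2 * (l20 + x4))
                        p4 = (F14 - F24) * v4
                        x2_, v2_ = y2[0], y2[1]
                        F12 = A1 + B1 * (l10 - x2_) + y2[2] * (C1 + D1 * (l10 - x2_))
                        F22 = A2 + B2 * (l20 + x2_) + y2[4] * (C2 + D2 * (l20 + x2_))
                        pm = (F12 - F22) * v2_
                        work += dt / 6.0 * (p1 + 4.0 * pm + p4)
                    y = tuple(
                        y[j] + dt / 6.0 * (k1[j] + 2 * k2[j] + 2 * k3[j] + k4[j])
                        for j in range(6)
                    )
        return work

    n_free = n_intervals * (int(act1) + int(act2))
    if u0 is None:
        # antiphase 40%-duty bursts as the starting point
        base = np.zeros(n_intervals)
        base[: int(0.4 * n_intervals)] = 1.0
        parts = []
        if act1:
            parts.append(base)
        if act2:
            parts.append(np.roll(base, n_intervals // 2))
        u0 = np.concatenate(parts) if parts else np.zeros(0)
    if n_free == 0:
        raise ValueError("no active muscle to optimize")

    res = minimize(
        lambda u: -simulate(u), u0, method="L-BFGS-B",
        bounds=[(0.0, 1.0)] * n_free,
        options={"maxiter": maxiter, "ftol": 1e-10, "gtol": 1e-8},
    )
    return {
        "cyclic_work_J": float(-res.fun),
        "mean_power_W": float(-res.fun) * problem.frequency,
        "controls": res.x,
        "n_intervals": n_intervals,
        "success": bool(res.success),
    }
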