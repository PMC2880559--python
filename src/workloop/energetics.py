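"""Workloop energetics: cyclic work, dissipation, synergy, impedance matching.

A workloop is the closed curve traced by contractile force versus
displacement over one steady-state cycle; its signed (shoelace) area is the
net mechanical work done per cycle, counter-clockwise loops meaning positive
work by the muscle.  At a periodic steady state the stored energy returns to
its starting value each cycle, so cyclic muscle work equals the energy
dissipated in the load damper.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .load_dynamics import LoadParams, Trajectory

__all__ = [
    "Workloop",
    "SynergyMeasurement",
    "cyclic_work",
    "cyclic_work_from_trajectory",
    "damper_dissipation",
    "synergy_ratio",
    "matched_stiffness",
    "normalized_power_table",
    "segment_cycles",
]

#: a cycle whose endpoints differ by more than this fraction of its force
#: excursion is treated as open (not at steady state)
CLOSURE_TOL = 0.01


def segment_cycles(t: np.ndarray, period: float, t0: float = 0.0) -> list[np.ndarray]:
    """Index masks for complete cycles of the given period starting at t0.

    Cycles are segmented by the stimulus-waveform period rather than by
    zero crossings, which is robust to displacement offsets.
    """
    cycles = []
    n = int(np.floor((t[-1] - t0) / period + 1e-9))
    for i in range(n):
        lo, hi = t0 + i * period, t0 + (i + 1) * period
        mask = (t >= lo - 1e-12) & (t <= hi + 1e-12)
        if mask.sum() >= 8:
            cycles.append(np.nonzero(mask)[0])
    return cycles


@dataclass
class Workloop:
    """Force–displacement samples of one or more contraction cycles."""

    force: np.ndarray
    displacement: np.ndarray
    cycles: list[np.ndarray] = field(default_factory=list)  # index arrays

    def __post_init__(self) -> None:
        self.force = np.asarray(self.force, dtype=float)
        self.displacement = np.asarray(self.displacement, dtype=float)
        if self.force.shape != self.displacement.shape:
            raise ValueError("force and displacement must have equal shapes")
        if not self.cycles:
            self.cycles = [np.arange(self.force.size)]

    @classmethod
    def from_trajectory(cls, traj: Trajectory, period: float, t0: float = 0.0,
                        which: str = "net") -> "Workloop":
        force = {"net": traj.Fnet, "agonist": traj.F1, "antagonist": traj.F2}[which]
        # agonist shortens along +x, so plot against its own shortening; net
        # force already acts along +x
        disp = traj.x if which != "antagonist" else -traj.x
        return cls(force=force, displacement=disp,
                   cycles=segment_cycles(traj.t, period, t0))


def _loop_area(f: np.ndarray, x: np.ndarray) -> float:
    """Signed shoelace area of the (x, f) polygon: ∮ f dx (J)."""
    x_c = np.concatenate([x, x[:1]])
    f_c = np.concatenate([f, f[:1]])
    return float(0.5 * np.sum((f_c[1:] + f_c[:-1]) * (x_c[1:] - x_c[:-1])))


def cyclic_work(loop: Workloop, frequency: float | None = None,
                closure_tol: float = CLOSURE_TOL) -> dict:
    """Work per cycle (J) from the loop area, and mean power (W) if the
    cycle frequency is given.

    Counter-clockwise loops (force leading shortening) give positive work.
    Cycles that fail to close within ``closure_tol`` of their excursion
    (default 1%; pass inf to keep transients, as session averaging does)
    are excluded from the averages with a warning.
    """
    works = []
    open_cycles = 0
    for idx in loop.cycles:
        f, x = loop.force[idx], loop.displacement[idx]
        # closure gap per axis, allowing one sample step of slack so that
        # grids sampled without the duplicate endpoint still count as closed
        ptp_f, ptp_x = max(np.ptp(f), 1e-30), max(np.ptp(x), 1e-30)
        step_f = np.max(np.abs(np.diff(f))) if f.size > 1 else 0.0
        step_x = np.max(np.abs(np.diff(x))) if x.size > 1 else 0.0
        open_f = abs(f[-1] - f[0]) > closure_tol * ptp_f + 1.5 * step_f
        open_x = abs(x[-1] - x[0]) > closure_tol * ptp_x + 1.5 * step_x
        if open_f or open_x:
            open_cycles += 1
            continue
        works.append(_loop_area(f, x))
    if open_cycles:
        warnings.warn(f"{open_cycles} open cycle(s) excluded from workloop averages")
    if not works:
        raise ValueError("no closed cycles in workloop")
    work = float(np.mean(works))
    out = {"work_J": work, "per_cycle_J": works, "n_open": open_cycles}
    if frequency is not None:
        out["mean_power_W"] = work * frequency
    return out


def cyclic_work_from_trajectory(
    traj: Trajectory, period: float, t0: float = 0.0, which: str = "net"
) -> dict:
    """Cyclic work of a trajectory's force loop at the stimulus period."""
    loop = Workloop.from_trajectory(traj, period, t0, which=which)
    return cyclic_work(loop, frequency=1.0 / period)


def damper_dissipation(traj: Trajectory, load: LoadParams, period: float,
                       t0: float = 0.0) -> dict:
    """Energy dissipated in the damper per cycle: ∫ b v² dt (J)."""
    v = traj.v
    energies = []
    for idx in segment_cycles(traj.t, period, t0):
        energies.append(float(np.trapezoid(load.b * v[idx] ** 2, traj.t[idx])))
    if not energies:
        raise ValueError("trajectory shorter than one cycle")
    return {"energy_J": float(np.mean(energies)), "per_cycle_J": energies}


@dataclass(frozen=True)
class SynergyMeasurement:
    """Cyclic works of agonist alone, antagonist alone, and the pair (J)."""

    W1: float
    W2: float
    W12: float

    @property
    def ratio(self) -> float:
        return synergy_ratio(self)


def synergy_ratio(m: SynergyMeasurement) -> float:
    """S = W12 / (W1 + W2); defined only for W1 + W2 > 0."""
    if not np.isfinite([m.W1, m.W2, m.W12]).all():
        raise ValueError("works must be finite")
    if m.W1 + m.W2 <= 0:
        raise ValueError("synergy ratio undefined for W1 + W2 <= 0")
    return m.W12 / (m.W1 + m.W2)


def matched_stiffness(load: LoadParams, omega: float) -> dict:
    """Source stiffness nulling the combined reactance at drive frequency omega.

    A stiffness-dominated source has purely reactive impedance -k_s/omega;
    maximal power transfer requires the source reactance to cancel the load
    reactance M*omega - k/omega, giving k_s = M*omega**2 - k.  Below the
    load's own resonance this would be negative; it is clamped at zero and
    flagged, since activation can only add stiffness in this model.  The
    combined natural frequency sqrt((k + k_s)/M)/2π equals omega/2π when
    unclamped.
    """
    if omega <= 0:
        raise ValueError("omega must be positive")
    k_s = load.M * omega**2 - load.k
    clamped = k_s < -1e-9 * load.k
    if k_s < 0:
        k_s = 0.0
    f_combined = np.sqrt((load.k + k_s) / load.M) / (2 * np.pi)
    return {"k_s": float(k_s), "f_combined_Hz": float(f_combined), "clamped": bool(clamped)}


def normalized_power_table(
    measurements: pd.DataFrame,
    f_n: float,
    freq_tol: float = 1e-6,
) -> dict:
    """Normalize per-set power measurements by each set's power at f_n.

    ``measurements`` needs columns set_id, freq_Hz, power_W.  Each
    measurement is divided by the P(f_n) of its own set, so the normalized
    power at f_n is identically 1 with zero variance by construction; sets
    without a positive P(f_n) entry are excluded with a warning.  Returns
    the per-measurement table plus per-frequency means, SDs and one-sample
    two-sided t-tests against 1.
    """
    rows = []
    for set_id, grp in measurements.groupby("set_id"):
        at_fn = grp[np.abs(grp["freq_Hz"] - f_n) <= freq_tol]
        if at_fn.empty or not (at_fn["power_W"].iloc[0] > 0):
            warnings.warn(f"set {set_id!r} lacks a positive P(f_n) normalizer; excluded")
            continue
        p_fn = float(at_fn["power_W"].iloc[0])
        for _, r in grp.iterrows():
            rows.append(
                {"set_id": set_id, "freq_Hz": float(r["freq_Hz"]),
                 "power_W": float(r["power_W"]),
                 "normalized_power": float(r["power_W"]) / p_fn}
            )
    if not rows:
        raise ValueError("no usable measurement sets")
    table = pd.DataFrame(rows)
    summary = {}
    for f, grp in table.groupby("freq_Hz"):
        vals = grp["normalized_power"].to_numpy()
        entry = {"mean": float(vals.mean()), "sd": float(vals.std(ddof=1)) if len(vals) > 1 else 0.0,
                 "n": int(len(vals))}
        if len(vals) > 1 and entry["sd"] > 0:
            t, p = stats.ttest_1samp(vals, 1.0)
            entry.update(t=float(t), p=float(p))
        summary[float(f)] = entry
    return {"table": table, "summary": summary}
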