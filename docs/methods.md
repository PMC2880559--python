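# Methods

`workloop` models the mechanical energetics of one or two skeletal muscles
driving a second-order load, solves for the cyclic stimulation pattern that
maximizes power transfer, and emulates the corresponding virtual-load
experiments on synthetic data. This note records the model, the numerical
scheme, the default calibration, and the limits of what the synthetic
pipeline demonstrates.

## Model

**Excitation–contraction dynamics.** Each muscle's activation `a` follows a
cascade of two first-order stages with real poles,

    tau_c * dc/dt = gain * u - c
    tau_a * da/dt = c - a,

representing calcium release/diffusion and re-uptake. The stimulus `u` is
bounded in [0, 1]; with unity DC gain the states stay in [0, 1]. Defaults
are equal poles `tau_c = tau_a = 0.125 s`, the simplest two-parameter
member that puts the twitch rise (stimulus onset to peak) at 125 ms. With
equal poles the fall time (peak to 10% of peak) is pinned at ≈3.9× the
rise; `calibrate_activation_params` matches the rise exactly for any pole
ratio and reports the fall residual with a warning when the requested pair
is outside the family.

Conventions the package uses throughout (the literature rarely defines
them): *rise time* = stimulus onset → twitch peak; *fall time* = peak → 10%
of peak.

**Bilinear contractile force.** Muscle force is bilinear in length and
activation,

    F(l, a) = A + B*l + a*(C + D*l),

so stiffness `B + D*a` is linear in activation — the property that lets
neural input retune the resonance of the coupled system. No force–velocity
curve, tendon elasticity or recruitment model is included; the bilinearity
*is* the modeling commitment. The model is trusted within ±10% of the
nominal length `l0`; outside, `muscle_force` warns and extrapolates.

**Load and coupling.** The load is `M x'' + b x' + k x = F_net`, with
`F_net = F1(l1, a1) − F2(l2, a2)`, `l1 = l1,0 − x`, `l2 = l2,0 + x`:
positive displacement shortens the agonist. The single-muscle system is
the special case with the antagonist's force coefficients zeroed. Defaults:
`f_n = 2 Hz`, `zeta = 0.1`, `k = 1000 N/m` (mid-range of the 750–1500 N/m
regime where load and muscle stiffness are commensurate); `M` and `b`
derived. The damping ratio is a package choice — figure-level values are
not published — and is config-overridable.

## Default muscle calibration

Published work fixes only the twitch times, the stiffness regime, and the
observation that the power-optimal frequency sits near 1.2·f_n; no numeric
A, B, C, D are printed. The defaults are therefore calibrated, not
transcribed:

- Impedance matching at 1.2·f_n requires an added source stiffness
  `(1.2² − 1)k = 0.44k`. Taking the cycle-average activation of a
  power-optimal burst as `a_ref = 0.5` (bang-bang solutions run near 50%
  duty and the cascade has unity DC gain), `B + D·a_ref = 0.44k` with a
  small passive share gives `B = 55 N/m`, `D = 825 N/m`. Full-activation
  stiffness `B + D = 880 N/m` lands inside the muscle-stiffness regime.
- The active force scale is set by strain viability, not by maximal
  tetanic force: at matched resonance the load is purely resistive, so a
  ±10% strain of `l0 = 25 mm` bounds the net drive at roughly
  `b·omega·x ≈ 0.5 N`. `C` is chosen so the full-activation contractile
  force at nominal length is 2 N (`C = 2 − D·l0 = −18.625 N`; the offset
  `A = 0` keeps force non-negative across the operating range). Forces of
  tens of newtons — physiological for an isometric tetanus — are
  incompatible with viable strains under this load and are deliberately
  not targeted.

A consequence worth knowing: because `C + D·l` is a small difference of
large terms, the effective drive amplitude is sensitive to the operating
length — shifting the equilibrium by 1 mm changes the drive by ~40%. This
is inherent to a bilinear law whose stiffness must rival the load's while
its force stays at the newton scale.

With this calibration the frequency sweeps put the power optimum at
`f*/f_n ≈ 1.15` (2.3 Hz on the 2 Hz load, 4.6 Hz on the 4 Hz load): the
*strict* resonance tuning `f* > f_n` always holds for `D > 0`, but the
phase-locked, time-varying stiffness is somewhat less effective than its
cycle average, so the realized ratio falls slightly below the static
matching estimate of 1.2. The calibration was fixed from the static
argument above and intentionally not iterated against the sweep outcome.

## Power-optimal cyclic control

The cyclic work `∮ F_net dx` over one period `T = 1/f` is maximized over
bounded stimuli. With running cost `L = −F_net·v` the Hamiltonian
`H = L + λᵀf` is linear in each `u_i`, so the minimum principle gives a
bang-bang law: `u_i = u_max` where the switching function
`σ_i = gain·λ_{c,i}/tau_c` is negative, `u_min` where positive, ties broken
to `u_min`. States and costates satisfy a 12-dimensional ODE system with
cyclic boundary conditions.

**Numerical scheme.** Discontinuous controls defeat generic collocation,
so the solver uses a smoothing homotopy: the bang-bang law is replaced by
`u = u_min + Δ·expit(−β σ/s)` (with `s` an RMS normalization of σ frozen
per solve) and β is continued over 10 → 10⁴; at the final sharpness fewer
than 2% of nodes are more than `1e−3·Δ` off a bound. Each stage is solved
with `scipy.integrate.solve_bvp` on normalized time with analytic
Jacobians.

Two degeneracies required care. The sigmoid law is the exact argmin of an
entropy-regularized Hamiltonian, so the smoothed closed-loop field
*conserves* that Hamiltonian: cyclic orbits inherit the degeneracies of a
conservative system (time-shift invariance plus a doubled unit Floquet
multiplier). The BVP is regularized the way periodic orbits of
conservative systems are continued: an unfolding parameter `p` adds
artificial damping along the Hamiltonian gradient `∇H = (−λ̇, f)` — any
periodic orbit then forces `p = 0`, observed at ~1e−11 — and the phase is
anchored by the boundary condition `v(0) = 0` (the guess is rolled to a
`v≈0, x>0` phase so the solver converges to that representative; reported
energetics are phase-invariant).

**Initial guesses and continuation.** Cold starts simulate antiphase
rectangular bursts (40% duty, burst phase picked by a coarse work scan) to
a near-periodic cycle, then solve the *linear periodic adjoint problem*
along that frozen trajectory for consistent costates. Frequency sweeps
start at the grid point nearest `f_n` and continue outward, warm-starting
each solve from its neighbor at full sharpness (falling back to the β
ladder on failure). Solutions report boundary residuals, collocation
residuals (tolerance 1e−4, polished at 1e−5), Hamiltonian variation
(constant to <1% on converged solutions), a trivial-solution flag, and a
possibly-singular flag when a switching function hugs zero for >5% of the
cycle. The solver itself draws no random numbers.

**Independent checks.** Three oracles guard the solver: a
finite-difference check of the costate equations; a direct transcription
(piecewise-constant controls, fixed-step RK4 to steady state, L-BFGS-B)
that independently reaches the BVP's cyclic work within 2%; and the
analytic Fourier benchmark below, which the `D = 0` reduction of the
muscle problem must reproduce.

## Impedance-free benchmark and impedance matching

For a force source bounded by `|F| ≤ F_max` on the linear load, the
power-optimal periodic forcing at a given frequency is the symmetric
square wave locked to the velocity sign; its mean power follows from the
per-harmonic steady state, `P = Σ_h ½|F_h|² b/|Z(jhω)|²`. The optimum over
frequency is `f_n`, and two equal sources give a synergy ratio
`S = W12/(W1+W2)` of exactly 2 at every frequency; unequal bounds give
`S = (1+r)²/(1+r²) ∈ (1, 2]`. Muscles beat this bound only through
activation-dependent stiffness. The matching algebra is exposed directly:
`matched_stiffness` returns `k_s = Mω² − k`, clamped at zero below `f_n`
(activation can only add stiffness) and flagged when clamped.

## Emulated experiments

The synthetic pipeline reproduces the structure of virtual-load sessions:

- **Stimulation**: waveforms periodic at the oscillation frequency; within
  burst windows a 200 Hz train of 100 µs pulses at full recruitment. The
  pulse rate is far above the cascade bandwidth (1/tau ≈ 8 Hz), so the
  model input is the fused recruitment envelope (u = 1 inside bursts);
  feeding the raw 2%-duty train into the linear cascade would contradict
  the full-recruitment premise. Burst windows default to the on-intervals
  of the optimal-control solution, quantized to the pulse grid; a cheap
  fixed-duty, phase-scanned schedule is available for bulk runs.
- **Sessions**: measurements repeat 5–7 times (6 by default), each
  recording 7 cycles from rest with the first discarded and the rest
  averaged (transient cycles are kept in the average, as the bench
  procedure does). Condition order is randomized per set to decorrelate
  fatigue from condition; fatigue multiplies the active coefficients C, D
  by (1 − 0.01) per measurement; recorded force carries additive Gaussian
  noise of SD 2% of peak force and position 0.1% of excursion. All noise
  magnitudes and the fatigue law are package choices (the apparatus values
  are unpublished) and are config-exposed. Ground-truth noiseless traces
  are retained, and the zero-noise, zero-fatigue emulation is bit-identical
  to direct simulation.
- **Hypothesis protocols**: H1 measures a lone muscle (no antagonist
  attached) at {f_n, f_opt, f_high} = {2, 2.5, 3} Hz (or {4, 5, 6}),
  normalizes each set by its own P(f_n), and tests normalized P(f_opt)
  against 1 and against P(f_high). H2 measures agonist-only,
  antagonist-only (attached but unstimulated), and both-muscle conditions
  on the same load — contralateral pairs drawn with ~5% parameter spread —
  and tests S against 2. The threshold tests are one-sample two-sided
  t-tests with (*) p<0.05 and (**) p<0.01; the underlying publications do
  not name their test, so this choice is documented rather than inherited.
- **Identification**: sinusoidal length trajectories (1–6 Hz, two or more
  amplitudes) are imposed in motion-source mode with stimulation triggered
  at fixed phases; activation is estimated as the superposition of
  normalized twitch profiles, and force from the bilinear law plus noise.
  Because the same activation construction is used on both sides,
  zero-noise identification recovers the generating coefficients to 1e−8,
  and the {offset, length, activation, activation×length} reduction loses
  almost no variance against the generalized model with small velocity
  terms.

## What the synthetic results do and do not show

The generator emulates the *structure* of bench sessions, not frog muscle:
passing tests demonstrate that the analysis pipeline is internally
consistent (normalization identities, randomization, fatigue handling,
recovery of known parameters), not that the model reproduces in vitro
power levels. Absolute powers (~mW; ~W/kg for gram-scale muscles) are
below the 17–81 W/kg reported on the bench, as expected from the
strain-limited force calibration, and no acceptance value targets them.

Two limitations matter when reading synergy numbers. First, the paired
optimal-control solutions between roughly 2.5 and 3.5 Hz drive
displacements beyond the ±10% operating range of the force law; there the
model's muscles extrapolate through zero force, and the synergy ratio of
the *unconstrained optima* becomes arbitrarily large (S ~ 10²) because the
single-muscle denominator collapses above its own matching range. Such
solutions carry `meta["within_operating_range"] = False` and should be
read as "the pair vastly outperforms twice the single muscle here", not as
a quantitative ratio. Burst-schedule emulations that stay in range give
S ≈ 2.2–2.6 above f_n — greater than 2, the qualitative claim — and S ≈ 2
for `D = 0` surrogates. Second, with the documented calibration the sweep
optimum sits at 1.15·f_n rather than the printed 1.2·f_n (see above); the
strict inequality `f* > f_n` is the robust prediction.

## Problem sizes and tolerances

Defaults chosen for routine runs: coupled simulations at rtol 1e−8 /
atol 1e−10 with ≥200 nodes per cycle (1e−7/1e−9 inside emulated sessions);
collocation tolerance 1e−4 with a 1e−5 polish and ≤8000 mesh nodes;
homotopy ladder β ∈ {10, 40, 160, 640, 2560, 10240}; sweeps on 0.1 Hz
grids for f* and 0.5 Hz grids (1.5–6 Hz) for synergy; transcription oracle
with 20 control intervals per cycle, 8 settling cycles. Energy bookkeeping
on simulated trajectories closes to <1e−4 relative; cyclic work matches
damper dissipation to <0.5% on converged optima.
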