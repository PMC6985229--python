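# Methods

## Model and scope

The package implements the classical Hodgkin–Huxley (HH) membrane model for
a space-clamped neuron and a minimal two-neuron feed-forward system. The
state of one neuron is (V, m, h, n); ionic currents are written
g·(E − V), so depolarizing currents are positive, and all rate laws depend
on the voltage only through the offset x = V − V_rest. Units are fixed
globally — mV, ms, μA/cm², mS/cm², μF/cm² — so that 1 μF/cm² × 1 mV/ms =
1 μA/cm². The rate-law prefactors (0.1, 0.01) carry units of 1/(ms·mV),
making every rate 1/ms, consistent with the classical formulation.

Out of scope by design: temperature scaling, stochastic channels,
multi-compartment cables, bidirectional or N > 2 coupling, bifurcation and
chaos analysis, and conductance-based (reversal-potential) chemical
synapses.

## Removable singularities

α_m and α_n are 0/0 at offsets x = 25 and x = 10 mV. Both are evaluated
through `expm1` (accurate denominators arbitrarily close to the
singularity) and replaced by their analytic limits (1.0 and 0.1) inside a
guard band |x − x₀| < 1e−7 mV, keeping the rates continuous without a
branch-induced jump. The same treatment applies to their voltage
derivatives in the Jacobian (limits 1/20 and 1/200).

## Resting equilibrium

At zero current the fixed point satisfies x = x∞(V) for each gate and
V = (Σ gᵢEᵢ)/(Σ gᵢ). Two modes are exposed:

- **one-shot** (`one_shot_equilibrium`): gates at x∞(V_rest), then a single
  voltage update. This is the literal closed-form arithmetic and yields
  V = −64.9995 mV for the default parameters.
- **converged** (`find_equilibrium`, the default elsewhere): damped
  alternation `gates ← x∞(V)`, `V ← V + λ(V_target − V)` with λ = 1/2,
  tol 1e−9 mV on the undamped update, max 100 sweeps. Damping matters away
  from the default parameters: the raw alternation enters a two-cycle when
  the voltage map's slope drops below −1 (observed already at E_K ≈ −87 mV);
  the damped map stays contractive there and the fixed point is unchanged.
  Non-convergence raises an error carrying the last iterate.

The model as stated carries a small self-consistency gap: the rate laws pin
the gates to the *nominal* V_rest = −65 mV while the weighted-mean voltage
comes out at −64.9995 mV (converged: −64.9997 mV). The gap (< 1 μV of
drive) is a property of the formulation and is preserved, not corrected.
Residuals are reported per state component (mV/ms for V, 1/ms for gates)
rather than aggregated, because the units differ.

A third evaluation point, `nominal_equilibrium`, pins V to V_rest exactly
with gates at x∞(V_rest). This is the point at which linearizations quoted
against the nominal resting potential are evaluated; at the converged point
the fast-gate diagonal entry −(α_m+β_m) already moves in its 4th decimal.

## Stability analysis

`analytic_jacobian` implements the general partial derivatives of the
right-hand side (valid at any state), not constants specialized to the
resting point; the printed reference matrix then serves as a numeric
regression check. Structure: the gate rows couple only to V and to
themselves, so six off-diagonal entries are identically zero. A
central-difference Jacobian (`numeric_jacobian`, step 1e−6, second order)
is the independent oracle; the two agree entry-wise to 1e−4 (relative,
floored at 1e−8) across ±20% parameter perturbations.

Eigenvalues are sorted by ascending real part (ties by imaginary part) and
compared as multisets. Classification follows the Lyapunov indirect
method with tol = 1e−9 on the largest real part: strictly negative →
asymptotically stable, strictly positive → unstable, otherwise
inconclusive — the strictness guard keeps the verdict from flipping on
rounding. The coordinate shift that moves the equilibrium to the origin is
not materialized: the Jacobian at the equilibrium equals the Jacobian of
the shifted system at zero.

A reproducibility caveat on the reference values: the published 4-decimal
matrix and its published spectrum are mutually consistent only at the
~1e−3 level (the matrix's own eigenvalues differ from the published
spectrum by up to 7e−4, so no implementation can link the two at 4
decimals). Our full-precision spectrum agrees with the published one to
~7e−4; the unit tests freeze our computed values and document the ~1e−3
agreement explicitly.

## Integration

Classical fixed-step RK4; no adaptivity, no implicit solver, no in-loop
event detection — fidelity to the stated method is preferred over solver
sophistication. Default dt = 0.01 ms: spike-peak times are reported to
0.01 ms, so the grid must resolve that precision; horizons are ≤ 50 ms and
every state is stored (no thinning).

Stimulus sampling: the rectangular pulse is active on the half-open
interval [onset, onset+width), so its integrated duration equals the width
exactly on any grid, and all reference scenarios place pulse edges on grid
nodes. Stages k1–k3 sample the pulse at their own times; the k4 stage, at
the step's right endpoint, samples the pulse's *left limit* within the step
(active iff onset < t+dt ≤ onset+width). The value exactly at a
node-aligned jump belongs to the next step; using it inside the current
step injects an O(dt²) local error at each pulse edge, which the
regenerative spike upstroke amplifies by two to three orders of magnitude.
Measured consequences of left-limit sampling at the default grid: the
dt = 0.01 vs 0.001 ms trajectory difference drops from ~0.5 mV to ~2e−4 mV,
and the step-halving convergence ratio across a pulsed run is ~15 (clean
order 4) instead of ~2. Order-of-convergence tests additionally use a
smooth scenario (zero-amplitude stimulus from an off-equilibrium state)
where no discontinuity is present at all.

Gate variables are not clipped; trajectories are checked against [0, 1]
(tolerance 1e−9) as a test invariant. Overflow or non-finite states raise
a blow-up error tagged with the failure time and the neuron label.

## Synapses and the pair simulation

Coupling currents: chemical `G_syn·H(V_pre(t−τ) − V_thresh)` with a
right-continuous Heaviside (H(0) = 1: a presynaptic potential exactly at
threshold counts as activation); electrical `G_syn·(V_pre(t−τ) − V_post)`;
simplified `G_syn·(V_pre(t) − V_rest,post)` (by construction it ignores
the delay). Units of G_syn: mS/cm² for the electrical and simplified
kinds, a bare current amplitude μA/cm² for the chemical kind — the
chemical model is dimensionally loose as stated and is implemented as
stated. Defaults: τ = 0, V_thresh = 0 mV (no reference value exists for
the threshold; 0 mV separates spikes from subthreshold activity at these
parameters). G_syn = 0 or kind "none" reduces the pair to two independent
neurons *bitwise* (the synapse hook then contributes an exact 0.0 to the
stage currents).

The pair is integrated in two passes on one shared grid rather than as a
joint 8-state system: the coupling is strictly feed-forward, so the
posterior neuron reads V_pre(t−τ) from the stored pass-1 trajectory
(linear interpolation; reads before the grid start clamp to the initial
potential). At τ = 0 the full-step stage reads are grid-aligned and exact;
mid-step stages interpolate linearly, which keeps the two-pass result
within the reporting precision of a joint integration while supporting
τ > 0 with no delay-differential machinery.

## Spike detection and sweeps

A spike is a local maximum of V at or above 0 mV (rest sits near −65 mV
and action potentials overshoot 0 mV, so 0 is a robust separator);
candidates closer than 2 ms are thinned greedily, higher peak first, so a
shoulder riding on a spike is not double-counted. Both knobs are
configurable since no reference criterion exists. Spike time is the grid
time of the maximum sample, with no sub-grid interpolation — at dt =
0.01 ms the grid matches the reporting precision. Peak amplitude is
reported both absolute and relative to the resting potential because the
natural baseline is question-dependent.

Coupling-strength sweeps re-run the pair per weight with everything else
fixed. The default sweep grid is 0 to 0.8 in steps of 0.05 plus {1, 2, 3}
(no reference grid is stated; this resolves the fast-drop region of the
latency curve and covers the two-spike regime).

## Scenarios, fixtures and problem sizes

Scenario files are TOML (preferred) or JSON; unknown keys are rejected at
every level. Defaults: 50 ms horizon at dt = 0.01 ms, τ = 0, V_thresh = 0.
Pair scenarios clone one neuron block into both roles (the reference
experiments always use identical neurons); heterogeneous pairs are
available programmatically. The built-in registry embeds the reference
experiments verbatim: three single-neuron initial-value cases
((−65, 0, 0, 0), (−65, 0.0529, 0.5961, 0.3177), (−65, 0.1, 0.7, 0.4))
under a 100 μA/cm² × 2 ms pulse at 4 or 15 ms; the four synapse-kind
comparisons at strength 4 with pulses at 10 ms (pre) and 12 ms (post); and
the two sweep scenarios.

All shipped computations are desk-scale: a 50 ms trajectory is 5000 RK4
steps (~25 ms wall time), the full sweep is 20 weights × two integrations
(~4 s), and the complete test suite plus acceptance script runs in well
under a minute on one CPU.

## Known limitations

- Fixed-step RK4 has no error control; pathological inputs (huge
  amplitudes, large dt) fail with a blow-up error rather than adapting.
- The delay implementation linearly interpolates the presynaptic history;
  delays far from grid multiples incur O(dt²) interpolation error.
- Spike times are grid-quantized (no sub-sample interpolation).
- The chemical synapse is the two-valued threshold model only; graded or
  conductance-based transmission is out of scope.
- Single equilibrium only: the solver tracks the resting point continued
  from V_rest and does not search for coexisting equilibria.
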