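# hhpair

Deterministic simulation and analysis of the classical Hodgkin–Huxley (HH)
neuron and of the simplest neuron *system*: two identical HH neurons coupled
one-way through a synapse. The package is aimed at computational
neuroscientists and engineers studying how pulse stimuli and synaptic
coupling shape action-potential timing — e.g. as a biological template for
interference-tolerant ("bio-inspired") circuit design.

## The model

A single space-clamped neuron has state (V, m, h, n): membrane potential
plus the sodium activation/inactivation and potassium activation gates,

```
C dV/dt = G_Na m³h (E_Na − V) + G_K n⁴ (E_K − V) + G_L (E_L − V) + I(t)
dx/dt   = α_x(V)(1 − x) − β_x(V) x          x ∈ {m, h, n}
```

with the classical squid-axon rate laws written in terms of the offset
V − V_rest (units: mV, ms, μA/cm², mS/cm², μF/cm²; defaults G_Na = 120,
G_K = 36, G_L = 0.3 mS/cm², E_Na = 50, E_K = −77, E_L = −54.4 mV, C = 1
μF/cm², V_rest = −65 mV). On top of the single neuron the package provides:

- **Resting equilibrium** — the self-consistent point where every gate sits
  at x∞ = α/(α+β) and V is the conductance-weighted mean of the reversal
  potentials, found by a damped alternating fixed-point iteration (plus the
  closed-form one-shot variant).
- **Stability** — the analytic 4×4 Jacobian of the autonomous system at the
  equilibrium, its eigenvalues, and a Lyapunov indirect-method verdict
  (asymptotically stable / unstable / inconclusive).
- **Integration** — fixed-step classical RK4 (default dt = 0.01 ms) with a
  rectangular pulse stimulus, preserving clean 4th-order convergence across
  grid-aligned pulse edges.
- **Coupling** — three synapse current models injected into a posterior
  neuron: chemical `G_syn·H(V_pre − V_thresh)`, electrical (gap junction)
  `G_syn·(V_pre − V_post)`, and a simplified form
  `G_syn·(V_pre − V_rest,post)`; the pair is strictly feed-forward.
- **Spike analysis** — peak detection, first-spike latency, and sweeps of
  the coupling strength ("connected weight").

## Worked example

```python
import hhpair as hp

params = hp.NeuronParams()                    # classical squid-axon values
eq = hp.one_shot_equilibrium(params)
print(round(eq.V, 4), round(eq.m, 4), round(eq.h, 4), round(eq.n, 4))
# -64.9995 0.0529 0.5961 0.3177

rep = hp.stability_report(params)
print(rep.classification, round(rep.margin, 4))
# asymptotically_stable -0.1207

# two identical neurons, 100 uA/cm2 x 2 ms pulses at 10 ms (pre) / 12 ms
# (post), simplified synapse
template = hp.builtin_fixtures()["fig6_simplified"].pair_config()
for w in (0.0, 0.8):
    traj = hp.simulate_pair(template.with_weight(w))
    t_spike = hp.first_spike_time(hp.detect_spikes(traj.t, traj.post.V))
    print(w, t_spike)
# 0.0 12.73
# 0.8 11.17
```

The equilibrium line is the resting point implied by the parameter table
(gates dimensionless, V in mV); the stability margin is the largest
eigenvalue real part (1/ms), negative, so the resting point attracts. The
pair lines show the posterior neuron's action-potential peak time (ms):
coupling it to the preceding neuron advances the spike, here by ≈ 12% at
weight 0.8. At weights ≥ 1 the posterior trace gains a second spike near
30–35 ms.

A CLI mirrors the library (`hhpair scenarios`, `hhpair equilibrium`,
`hhpair stability`, `hhpair simulate`, `hhpair pair`, `hhpair sweep`,
`hhpair reproduce <name>`); trajectories are written as CSV and reports as
JSON.

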