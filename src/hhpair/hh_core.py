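"""Core Hodgkin-Huxley biophysics for a single space-clamped neuron.

The model is the classical squid-axon description: a membrane capacitance in
parallel with sodium, potassium and leak branches, with the sodium channel
gated by activation ``m`` (cubed) and inactivation ``h``, and the potassium
channel by activation ``n`` (fourth power).  The state is ``(V, m, h, n)``
and the dynamics are

    C dV/dt = G_Na m^3 h (E_Na - V) + G_K n^4 (E_K - V) + G_L (E_L - V) + I
    dx/dt   = alpha_x(V) (1 - x) - beta_x(V) x        for x in {m, h, n}

Units are fixed globally: mV, ms, uA/cm^2, mS/cm^2, uF/cm^2 (so that
1 uF/cm^2 x 1 mV/ms = 1 uA/cm^2).  Ionic currents are written g*(E - V):
a positive applied current depolarizes.

The voltage-dependent rates are expressed relative to the resting potential
(offset ``x = V - V_rest``), so the whole model is translation-invariant:
shifting ``V`` and ``V_rest`` together changes nothing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "NeuronParams",
    "NeuronState",
    "GateRates",
    "PulseStimulus",
    "gate_rates",
    "channel_conductances",
    "pulse_current",
    "hh_rhs",
]

#: half-width (in mV of voltage offset) of the guard band inside which the
#: removable 0/0 singularities of alpha_m and alpha_n are replaced by their
#: analytic limits (1.0 and 0.1 respectively)
SINGULAR_BAND = 1e-7


@dataclass(frozen=True)
class NeuronParams:
    """Biophysical constants of one neuron.

    Defaults are the classical squid-axon values: maximal conductances
    (120, 36, 0.3) mS/cm^2, reversal potentials (50, -77, -54.4) mV,
    membrane capacitance 1 uF/cm^2 and resting potential -65 mV.
    """

    C: float = 1.0  # membrane capacitance, uF/cm^2
    G_Na: float = 120.0  # maximal sodium conductance, mS/cm^2
    G_K: float = 36.0  # maximal potassium conductance, mS/cm^2
    G_L: float = 0.3  # leak conductance, mS/cm^2
    E_Na: float = 50.0  # sodium reversal potential, mV
    E_K: float = -77.0  # potassium reversal potential, mV
    E_L: float = -54.4  # leak reversal potential, mV
    V_rest: float = -65.0  # resting potential entering the rate laws, mV

    def __post_init__(self) -> None:
        for name in ("C", "G_Na", "G_K", "G_L", "E_Na", "E_K", "E_L", "V_rest"):
            v = getattr(self, name)
            if not math.isfinite(v):
                raise ValueError(f"NeuronParams.{name} must be finite, got {v!r}")
        if self.C <= 0:
            raise ValueError(f"membrane capacitance must be positive, got {self.C}")
        for name in ("G_Na", "G_K", "G_L"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative, got {getattr(self, name)}")


@dataclass(frozen=True)
class NeuronState:
    """Instantaneous state ``(V, m, h, n)`` of one neuron.

    ``V`` is the membrane potential in mV; the gates are dimensionless
    probabilities.  Gate bounds are *not* enforced here (trajectories are
    checked against [0, 1] as an invariant, not clipped), but all components
    must be finite.
    """

    V: float
    m: float
    h: float
    n: float

    def __post_init__(self) -> None:
        for name in ("V", "m", "h", "n"):
            if not math.isfinite(getattr(self, name)):
                raise ValueError(f"NeuronState.{name} must be finite")

    def as_array(self) -> np.ndarray:
        return np.array([self.V, self.m, self.h, self.n], dtype=float)

    @classmethod
    def from_array(cls, a) -> "NeuronState":
        V, m, h, n = (float(x) for x in a)
        return cls(V, m, h, n)


@dataclass(frozen=True)
class GateRates:
    """The six voltage-dependent transition rates, all in 1/ms."""

    alpha_m: float
    beta_m: float
    alpha_h: float
    beta_h: float
    alpha_n: float
    beta_n: float


@dataclass(frozen=True)
class PulseStimulus:
    """A single rectangular current pulse.

    ``amplitude`` in uA/cm^2, ``onset`` and ``width`` in ms.  The pulse is
    active on the half-open interval [onset, onset + width), so its duration
    equals ``width`` exactly on any grid.
    """

    amplitude: float = 0.0
    onset: float = 0.0
    width: float = 0.0

    def __post_init__(self) -> None:
        for name in ("amplitude", "onset", "width"):
            if not math.isfinite(getattr(self, name)):
                raise ValueError(f"PulseStimulus.{name} must be finite")
        if self.onset < 0:
            raise ValueError(f"pulse onset must be >= 0, got {self.onset}")
        if self.width < 0:
            raise ValueError(f"pulse width must be >= 0, got {self.width}")


def _rates_scalar(x: float) -> tuple[float, float, float, float, float, float]:
    """Six rates as plain floats given the voltage offset x = V - V_rest.

    Hot path shared by the RHS, the integrator and the Jacobian; uses
    ``math.expm1`` so the alpha_m / alpha_n denominators stay accurate near
    their removable singularities (offsets 25 and 10 mV), which are patched
    with the analytic limits inside a +-SINGULAR_BAND guard band.
    """
    u = x - 25.0
    if abs(u) < SINGULAR_BAND:
        alpha_m = 1.0
    else:
        alpha_m = 0.1 * u / (-math.expm1(-u / 10.0))
    w = x - 10.0
    if abs(w) < SINGULAR_BAND:
        alpha_n = 0.1
    else:
        alpha_n = 0.01 * w / (-math.expm1(-w / 10.0))
    beta_m = 4.0 * math.exp(-x / 18.0)
    alpha_h = 0.07 * math.exp(-x / 20.0)
    beta_h = 1.0 / (1.0 + math.exp(-(x - 30.0) / 10.0))
    beta_n = 0.125 * math.exp(-x / 80.0)
    return alpha_m, beta_m, alpha_h, beta_h, alpha_n, beta_n


def gate_rates(V: float, V_rest: float) -> GateRates:
    """Evaluate the six gate transition rates at membrane potential ``V``.

    The rates depend on ``V`` only through the offset ``V - V_rest``.  All
    six are strictly positive and finite for any finite input; the 0/0
    points of alpha_m and alpha_n are patched by their limits.
    """
    if not (math.isfinite(V) and math.isfinite(V_rest)):
        raise ValueError("gate_rates requires finite V and V_rest")
    return GateRates(*_rates_scalar(V - V_rest))


def channel_conductances(state: NeuronState, params: NeuronParams) -> tuple[float, float]:
    """Instantaneous (gNa, gK) = (G_Na m^3 h, G_K n^4) in mS/cm^2."""
    g_na = params.G_Na * state.m**3 * state.h
    g_k = params.G_K * state.n**4
    return g_na, g_k


def pulse_current(t: float, stim: PulseStimulus) -> float:
    """Applied current at time ``t`` (half-open pulse support)."""
    if not math.isfinite(t):
        raise ValueError("pulse_current requires finite t")
    if stim.onset <= t < stim.onset + stim.width:
        return stim.amplitude
    return 0.0


def _rhs_scalar(
    V: float,
    m: float,
    h: float,
    n: float,
    C: float,
    G_Na: float,
    G_K: float,
    G_L: float,
    E_Na: float,
    E_K: float,
    E_L: float,
    V_rest: float,
    I: float,
) -> tuple[float, float, float, float]:
    """Unpacked-float right-hand side; hot path for the RK4 loop."""
    am, bm, ah, bh, an, bn = _rates_scalar(V - V_rest)
    g_na = G_Na * m * m * m * h
    g_k = G_K * n * n * n * n
    dV = (g_na * (E_Na - V) + g_k * (E_K - V) + G_L * (E_L - V) + I) / C
    return (
        dV,
        am * (1.0 - m) - bm * m,
        ah * (1.0 - h) - bh * h,
        an * (1.0 - n) - bn * n,
    )


def hh_rhs(state: NeuronState, params: NeuronParams, I: float = 0.0) -> np.ndarray:
    """Time derivative of the state under applied current ``I``.

    Returns ``[dV/dt, dm/dt, dh/dt, dn/dt]`` with dV/dt in mV/ms and the
    gate derivatives in 1/ms.
    """
    d = _rhs_scalar(
        state.V,
        state.m,
        state.h,
        state.n,
        params.C,
        params.G_Na,
        params.G_K,
        params.G_L,
        params.E_Na,
        params.E_K,
        params.E_L,
        params.V_rest,
        I,
    )
    return np.array(d, dtype=float)
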