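"""Resting-equilibrium (initial-value) computation.

At zero applied current the model has a resting fixed point where every
gate sits at its voltage-dependent steady state x_inf = alpha/(alpha+beta)
and the membrane potential is the conductance-weighted mean of the reversal
potentials.  The two relations are mutually dependent, so the point is
found by alternating them:

    gates <- gate_steady_state(V)
    V     <- resting_voltage(gates)

started from V = V_rest.  For the classical parameter set the alternation
converges in a few dozen sweeps to machine precision; a single alternation
(gates at V_rest, then one voltage update) already lands within 0.01 mV of
the converged point and is exposed as :func:`one_shot_equilibrium`.

Note the small self-consistency gap inherent to the formulation: the rate
laws pin the gate steady states to the *nominal* resting potential
V_rest = -65 mV, while the weighted-mean voltage comes out at -64.9995 mV.
That ~0.5 uV gap is a property of the model as stated and is deliberately
preserved, not corrected.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ConvergenceError, DegenerateInputError
from .hh_core import NeuronParams, NeuronState, gate_rates, hh_rhs

__all__ = [
    "EquilibriumPoint",
    "gate_steady_state",
    "resting_voltage",
    "find_equilibrium",
    "one_shot_equilibrium",
    "nominal_equilibrium",
]


@dataclass(frozen=True)
class EquilibriumPoint:
    """Self-consistent resting point ``(V, m, h, n)`` plus diagnostics.

    ``residual`` is the per-component right-hand side at the point with
    zero applied current (mV/ms for V, 1/ms for the gates) -- reported
    per component rather than aggregated because the units differ.
    """

    V: float
    m: float
    h: float
    n: float
    residual: tuple[float, float, float, float]
    iterations: int

    @property
    def state(self) -> NeuronState:
        return NeuronState(self.V, self.m, self.h, self.n)

    @property
    def max_abs_residual(self) -> float:
        return max(abs(r) for r in self.residual)


def gate_steady_state(V: float, V_rest: float) -> tuple[float, float, float]:
    """Steady gate values (m_inf, h_inf, n_inf) = alpha/(alpha+beta) at ``V``.

    Each component lies strictly inside (0, 1) for finite inputs and is the
    stationary point of its first-order gate kinetics at this voltage.
    """
    r = gate_rates(V, V_rest)
    return (
        r.alpha_m / (r.alpha_m + r.beta_m),
        r.alpha_h / (r.alpha_h + r.beta_h),
        r.alpha_n / (r.alpha_n + r.beta_n),
    )


def resting_voltage(m: float, h: float, n: float, params: NeuronParams) -> float:
    """Zero-current membrane potential for frozen gate values.

    Solves ``sum_i g_i (E_i - V) = 0`` for V, i.e. the conductance-weighted
    mean of the reversal potentials; the result always lies between the
    smallest and largest reversal potential.
    """
    g_na = params.G_Na * m**3 * h
    g_k = params.G_K * n**4
    denom = g_na + g_k + params.G_L
    if denom == 0.0:
        raise DegenerateInputError(
            "all channel conductances vanish; the resting voltage is undefined"
        )
    return (g_na * params.E_Na + g_k * params.E_K + params.G_L * params.E_L) / denom


def _residual(params: NeuronParams, V: float, m: float, h: float, n: float):
    r = hh_rhs(NeuronState(V, m, h, n), params, I=0.0)
    return tuple(float(x) for x in r)


def find_equilibrium(
    params: NeuronParams,
    tol: float = 1e-9,
    max_iter: int = 100,
    damping: float = 0.5,
) -> EquilibriumPoint:
    """Converged resting equilibrium by damped alternating fixed-point iteration.

    Alternates ``gates <- gate_steady_state(V)`` and
    ``V <- V + damping * (resting_voltage(gates) - V)`` from
    ``V = params.V_rest`` until the *undamped* voltage update falls below
    ``tol`` (mV).  The damping (default 1/2) is needed away from the
    classical parameter set: the raw alternation can enter a two-cycle when
    the voltage map's slope drops below -1 (seen e.g. for a ~13% more
    negative potassium reversal potential), while the damped map stays
    contractive there.  The fixed point itself is unaffected by damping.

    Raises
    ------
    ConvergenceError
        If ``|dV|`` has not dropped below ``tol`` after ``max_iter``
        alternations; the exception carries the last iterate in ``.last``.
    """
    if tol <= 0:
        raise ValueError(f"tol must be positive, got {tol}")
    if not 0.0 < damping <= 1.0:
        raise ValueError(f"damping must be in (0, 1], got {damping}")
    V = params.V_rest
    m = h = n = float("nan")
    for it in range(1, max_iter + 1):
        m, h, n = gate_steady_state(V, params.V_rest)
        V_target = resting_voltage(m, h, n, params)
        dV = abs(V_target - V)
        V = V + damping * (V_target - V)
        if dV < tol:
            return EquilibriumPoint(V, m, h, n, _residual(params, V, m, h, n), it)
    last = EquilibriumPoint(V, m, h, n, _residual(params, V, m, h, n), max_iter)
    raise ConvergenceError(
        f"equilibrium iteration did not converge to {tol} mV in {max_iter} sweeps",
        last=last,
    )


def one_shot_equilibrium(params: NeuronParams) -> EquilibriumPoint:
    """Single-alternation equilibrium: gates at V_rest, then one voltage update.

    This reproduces the literal two-step arithmetic of the closed-form
    initial-value calculation (gate steady states evaluated exactly at the
    nominal resting potential).  For the classical parameters it agrees with
    the converged point to well under 0.01 mV.
    """
    m, h, n = gate_steady_state(params.V_rest, params.V_rest)
    V = resting_voltage(m, h, n, params)
    return EquilibriumPoint(V, m, h, n, _residual(params, V, m, h, n), 1)


def nominal_equilibrium(params: NeuronParams) -> EquilibriumPoint:
    """The resting point with the voltage pinned to the nominal V_rest.

    Gates sit at their steady state for ``V = V_rest`` and the voltage is
    taken as ``V_rest`` itself (the conventional reading "the membrane
    rests at its resting potential").  The gate residuals are exactly zero;
    the voltage residual is the small zero-current imbalance left by the
    self-consistency gap (< 1e-3 mV/ms for the classical parameters).
    This is the evaluation point at which linearizations quoted against the
    nominal resting potential are computed.
    """
    V = params.V_rest
    m, h, n = gate_steady_state(V, V)
    return EquilibriumPoint(V, m, h, n, _residual(params, V, m, h, n), 0)
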