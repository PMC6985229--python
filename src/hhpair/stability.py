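"""Linear stability of the resting equilibrium (Lyapunov indirect method).

The autonomous system (zero applied current) is linearized at the resting
fixed point.  Because each gate's kinetics depend only on the voltage and
on itself, the 4x4 Jacobian in state order (V, m, h, n) has zero entries
wherever one gate would couple to another; the only dense parts are the
first row (voltage equation) and the first column (voltage dependence of
the rates).

Classification follows the indirect method: all eigenvalue real parts
strictly negative -> asymptotically stable; any strictly positive ->
unstable; a real part at the margin (within ``tol`` of zero) leaves the
method silent, reported as inconclusive.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .equilibrium import EquilibriumPoint, find_equilibrium
from .hh_core import SINGULAR_BAND, NeuronParams, NeuronState, hh_rhs, _rates_scalar

__all__ = [
    "ASYMPTOTICALLY_STABLE",
    "UNSTABLE",
    "INCONCLUSIVE",
    "StabilityReport",
    "analytic_jacobian",
    "numeric_jacobian",
    "eigen_spectrum",
    "classify",
    "stability_report",
]

ASYMPTOTICALLY_STABLE = "asymptotically_stable"
UNSTABLE = "unstable"
INCONCLUSIVE = "inconclusive"


def _rate_slopes(x: float) -> tuple[float, float, float, float, float, float]:
    """d(rate)/dV for the six rates at voltage offset x = V - V_rest.

    The alpha_m / alpha_n slopes have removable singularities at offsets 25
    and 10 mV, patched with their analytic limits (1/20 and 1/200).
    """
    u = x - 25.0
    if abs(u) < SINGULAR_BAND:
        d_alpha_m = 0.05
    else:
        D = -math.expm1(-u / 10.0)
        d_alpha_m = (0.1 * D - 0.01 * u * math.exp(-u / 10.0)) / (D * D)
    w = x - 10.0
    if abs(w) < SINGULAR_BAND:
        d_alpha_n = 0.005
    else:
        D = -math.expm1(-w / 10.0)
        d_alpha_n = (0.01 * D - 0.001 * w * math.exp(-w / 10.0)) / (D * D)
    d_beta_m = -(4.0 / 18.0) * math.exp(-x / 18.0)
    d_alpha_h = -(0.07 / 20.0) * math.exp(-x / 20.0)
    s = 1.0 / (1.0 + math.exp(-(x - 30.0) / 10.0))
    d_beta_h = s * (1.0 - s) / 10.0
    d_beta_n = -(0.125 / 80.0) * math.exp(-x / 80.0)
    return d_alpha_m, d_beta_m, d_alpha_h, d_beta_h, d_alpha_n, d_beta_n


def analytic_jacobian(params: NeuronParams, eq: EquilibriumPoint) -> np.ndarray:
    """Closed-form Jacobian of the autonomous system at the equilibrium.

    Implemented from the general partial derivatives of the right-hand side
    (valid at any state), then evaluated at ``eq``; row/column order is
    (V, m, h, n).
    """
    V, m, h, n = eq.V, eq.m, eq.h, eq.n
    p = params
    x = V - p.V_rest
    am, bm, ah, bh, an, bn = _rates_scalar(x)
    dam, dbm, dah, dbh, dan, dbn = _rate_slopes(x)

    g_na = p.G_Na * m**3 * h
    g_k = p.G_K * n**4

    J = np.zeros((4, 4))
    J[0, 0] = -(g_na + g_k + p.G_L) / p.C
    J[0, 1] = 3.0 * p.G_Na * m**2 * h * (p.E_Na - V) / p.C
    J[0, 2] = p.G_Na * m**3 * (p.E_Na - V) / p.C
    J[0, 3] = 4.0 * p.G_K * n**3 * (p.E_K - V) / p.C
    J[1, 0] = dam * (1.0 - m) - dbm * m
    J[1, 1] = -(am + bm)
    J[2, 0] = dah * (1.0 - h) - dbh * h
    J[2, 2] = -(ah + bh)
    J[3, 0] = dan * (1.0 - n) - dbn * n
    J[3, 3] = -(an + bn)
    return J


def numeric_jacobian(
    params: NeuronParams, eq: EquilibriumPoint, step: float = 1e-6
) -> np.ndarray:
    """Central-difference Jacobian of the zero-current right-hand side.

    Second-order accurate in ``step``; serves as the independent numerical
    oracle for :func:`analytic_jacobian`.
    """
    if step <= 0:
        raise ValueError(f"step must be positive, got {step}")
    s0 = np.array([eq.V, eq.m, eq.h, eq.n])
    J = np.empty((4, 4))
    for j in range(4):
        hi = s0.copy()
        lo = s0.copy()
        hi[j] += step
        lo[j] -= step
        f_hi = hh_rhs(NeuronState(*hi), params, I=0.0)
        f_lo = hh_rhs(NeuronState(*lo), params, I=0.0)
        J[:, j] = (f_hi - f_lo) / (2.0 * step)
    return J


def eigen_spectrum(J: np.ndarray) -> np.ndarray:
    """Eigenvalues of ``J`` sorted by ascending real part, then imaginary.

    For a real matrix the returned spectrum is closed under conjugation.
    """
    J = np.asarray(J, dtype=float)
    if not np.all(np.isfinite(J)):
        raise ValueError("eigen_spectrum requires a finite matrix")
    ev = np.linalg.eigvals(J)
    order = np.lexsort((ev.imag, ev.real))
    return ev[order]


def classify(spectrum: np.ndarray, tol: float = 1e-9) -> tuple[str, float]:
    """Indirect-method verdict from an eigenvalue spectrum.

    Returns ``(classification, margin)`` where ``margin`` is the maximum
    real part.  ``asymptotically_stable`` iff margin < -tol, ``unstable``
    iff margin > +tol, otherwise ``inconclusive`` (the linearization does
    not decide at the margin).
    """
    if tol < 0:
        raise ValueError(f"tol must be >= 0, got {tol}")
    margin = float(np.max(np.real(np.asarray(spectrum))))
    if margin < -tol:
        return ASYMPTOTICALLY_STABLE, margin
    if margin > tol:
        return UNSTABLE, margin
    return INCONCLUSIVE, margin


@dataclass(frozen=True)
class StabilityReport:
    """Full stability analysis of one neuron's resting point."""

    equilibrium: EquilibriumPoint
    jacobian: np.ndarray
    eigenvalues: np.ndarray
    classification: str
    margin: float

    def to_dict(self) -> dict:
        """JSON-ready form: matrix row-major, eigenvalues as [re, im] pairs."""
        return {
            "equilibrium": {
                "V": self.equilibrium.V,
                "m": self.equilibrium.m,
                "h": self.equilibrium.h,
                "n": self.equilibrium.n,
                "residual": list(self.equilibrium.residual),
                "iterations": self.equilibrium.iterations,
            },
            "jacobian": [list(map(float, row)) for row in self.jacobian],
            "eigenvalues": [[float(z.real), float(z.imag)] for z in self.eigenvalues],
            "classification": self.classification,
            "margin": self.margin,
        }


def stability_report(
    params: NeuronParams,
    eq: EquilibriumPoint | None = None,
    tol: float = 1e-9,
) -> StabilityReport:
    """Convenience pipeline: equilibrium -> Jacobian -> spectrum -> verdict."""
    if eq is None:
        eq = find_equilibrium(params)
    J = analytic_jacobian(params, eq)
    ev = eigen_spectrum(J)
    verdict, margin = classify(ev, tol=tol)
    return StabilityReport(eq, J, ev, verdict, margin)
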