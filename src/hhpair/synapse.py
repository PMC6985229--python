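"""Synapse current models coupling a preceding to a posterior neuron.

Three couplings behind one interface, all feed-forward (the presynaptic
neuron never feels the synapse):

``chemical``
    A thresholded constant: ``I = G_syn * H(V_pre(t - tau) - V_thresh)``
    with a right-continuous Heaviside (``H(0) = 1``: a presynaptic
    potential exactly at threshold counts as activation).  ``G_syn`` acts
    as a bare current amplitude (uA/cm^2); the model is implemented as
    stated even though its units are loose.

``electrical``
    A gap junction: ``I = G_syn * (V_pre(t - tau) - V_post)``; ``G_syn``
    is the gap conductance (mS/cm^2).

``simplified``
    A reduced coupling that replaces both the Heaviside and the
    postsynaptic feedback term: ``I = G_syn * (V_pre(t) - V_rest_post)``,
    i.e. proportional to the presynaptic deviation from the posterior's
    resting potential.  By construction it ignores the delay ``tau``.

``none`` forces a zero current regardless of the other fields, as does
``G_syn = 0`` for every kind, which decouples the pair exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = ["SYNAPSE_KINDS", "SynapseSpec", "synapse_current"]

SYNAPSE_KINDS = ("none", "chemical", "electrical", "simplified")


@dataclass(frozen=True)
class SynapseSpec:
    """Synapse kind plus its parameters.

    ``g_syn`` is the coupling strength ("connected weight"): a conductance
    in mS/cm^2 for the electrical and simplified kinds, a current amplitude
    in uA/cm^2 for the chemical kind.  ``v_thresh`` (mV) applies to the
    chemical kind only; ``tau`` (ms) is the transfer delay.
    """

    kind: str = "none"
    g_syn: float = 0.0
    v_thresh: float = 0.0
    tau: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in SYNAPSE_KINDS:
            raise ValueError(
                f"unknown synapse kind {self.kind!r}; expected one of {SYNAPSE_KINDS}"
            )
        if not all(map(math.isfinite, (self.g_syn, self.v_thresh, self.tau))):
            raise ValueError("SynapseSpec fields must be finite")
        if self.g_syn < 0:
            raise ValueError(f"g_syn must be >= 0, got {self.g_syn}")
        if self.tau < 0:
            raise ValueError(f"tau must be >= 0, got {self.tau}")


def synapse_current(
    spec: SynapseSpec,
    v_pre_delayed: float,
    v_post: float,
    v_rest_post: float,
) -> float:
    """Synapse current (uA/cm^2) injected into the posterior neuron.

    ``v_pre_delayed`` is the presynaptic potential already read at
    ``t - tau`` (the caller owns the delay bookkeeping; the simplified kind
    should be fed the undelayed ``V_pre(t)``).
    """
    kind = spec.kind
    if kind == "none":
        return 0.0
    if kind == "chemical":
        return spec.g_syn if v_pre_delayed >= spec.v_thresh else 0.0
    if kind == "electrical":
        return spec.g_syn * (v_pre_delayed - v_post)
    if kind == "simplified":
        return spec.g_syn * (v_pre_delayed - v_rest_post)
    raise ValueError(f"unknown synapse kind {kind!r}")  # pragma: no cover
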