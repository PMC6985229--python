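"""Exception types shared across the package."""


class HHPairError(Exception):
    """Base class for all hhpair-specific errors."""


class ConvergenceError(HHPairError):
    """An iterative solver failed to converge.

    Carries the last iterate in :attr:`last` so callers can inspect how far
    the iteration got.
    """

    def __init__(self, message: str, last=None):
        super().__init__(message)
        self.last = last


class NumericalBlowupError(HHPairError):
    """The integrator produced a non-finite state.

    :attr:`t` is the time at which the blow-up was detected, :attr:`label`
    names the neuron (``"pre"``/``"post"``/``"single"``) when known.
    """

    def __init__(self, message: str, t: float | None = None, label: str = "single"):
        super().__init__(message)
        self.t = t
        self.label = label


class DegenerateInputError(HHPairError, ValueError):
    """An input is structurally degenerate (e.g. all conductances zero)."""
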