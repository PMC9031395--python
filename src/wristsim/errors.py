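"""Exception hierarchy for wristsim."""


class WristSimError(Exception):
    """Base class for all wristsim errors."""


class ValidationError(WristSimError, ValueError):
    """Invalid configuration, parameter, or input data."""


class GeometryError(WristSimError):
    """Degenerate geometry (vanishing lever arm, flipped axis, ...)."""


class RangeError(WristSimError, ValueError):
    """Joint angle outside the admissible motion range."""


class InfeasibleLoadError(WristSimError):
    """The demanded joint torque cannot be produced within muscle strengths."""

    def __init__(self, message: str, axis: str | None = None, sample: int | None = None):
        super().__init__(message)
        self.axis = axis
        self.sample = sample


class ConvergenceError(WristSimError):
    """An iterative solver failed to reach its tolerance."""

    def __init__(self, message: str, residual: float | None = None):
        super().__init__(message)
        self.residual = residual
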