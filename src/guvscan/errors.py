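"""Exception hierarchy for guvscan."""


class GuvscanError(Exception):
    """Base class for all guvscan errors."""


class InputError(GuvscanError, ValueError):
    """Invalid user-supplied argument or data."""


class ModelInstabilityError(GuvscanError):
    """A circuit evaluation produced non-finite values; names the parameter."""

    def __init__(self, parameter: str, message: str = ""):
        self.parameter = parameter
        super().__init__(message or f"non-finite circuit response traced to parameter {parameter!r}")


class CalibrationError(GuvscanError):
    """Calibration failed to reach the requested tolerance."""

    def __init__(self, message: str, residuals=None):
        self.residuals = residuals
        super().__init__(message)


class OutOfLinearRangeError(GuvscanError, ValueError):
    """A capacitance perturbation exceeds the small-signal validity range."""


class SolverError(GuvscanError):
    """The electrostatic linear solve did not converge / is inconsistent."""

    def __init__(self, message: str, residual=None):
        self.residual = residual
        super().__init__(message)


class StateError(GuvscanError):
    """Operation requested on an object in the wrong state (e.g. unsolved map)."""


class RangeError(GuvscanError, ValueError):
    """Requested coordinate lies outside the simulated domain."""


class AnalysisError(GuvscanError):
    """Trace analysis cannot proceed (e.g. no baseline segment)."""


class DegenerateAnchorError(GuvscanError):
    """Gain calibration anchor produces a zero model response."""


class InversionError(GuvscanError):
    """Permittivity inversion failed to converge."""

    def __init__(self, message: str, trace=None):
        self.trace = trace
        super().__init__(message)
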