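"""Exception types shared across the solver stack."""


class MyoflowError(Exception):
    """Base class for all package errors."""


class ConfigurationError(MyoflowError):
    """A parameter set or mode flag is invalid."""


class GeometryError(MyoflowError):
    """A kinematic mapping left the admissible configuration space."""


class AssemblyError(MyoflowError):
    """The global fluid system is singular / under-constrained."""


class StepError(MyoflowError):
    """A nonlinear solve inside a time step failed to converge."""

    def __init__(self, message, residual_norms=None, time=None):
        super().__init__(message)
        self.residual_norms = residual_norms
        self.time = time


class SignalSpecError(MyoflowError):
    """An inlet-signal specification is malformed."""
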