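"""Exception hierarchy for sbmlkit.

All package-raised exceptions derive from :class:`SbmlError` so callers can
catch everything from one root.  The CLI maps subclasses to exit codes.
"""


class SbmlError(Exception):
    """Root of the sbmlkit exception hierarchy."""


class SbmlParseError(SbmlError):
    """Malformed XML or a non-SBML document."""


class SbmlFormatError(SbmlError):
    """Structurally invalid document for the requested operation."""


class UnsupportedPackageError(SbmlError):
    """A package declared with required="true" that this toolkit cannot read."""

    def __init__(self, prefix: str, namespace_uri: str):
        self.prefix = prefix
        self.namespace_uri = namespace_uri
        super().__init__(
            f"document requires unsupported package {prefix!r} ({namespace_uri}); "
            "it cannot be interpreted without it (use permissive=True to read anyway)"
        )


class MathError(SbmlError):
    """Base class for math-subsystem failures."""


class UnsupportedMathError(MathError):
    """A MathML element or operator outside the supported subset."""


class MathNameError(MathError):
    """An unbound symbol or undefined user function."""


class MathTypeError(MathError):
    """Boolean used where a number is required, or vice versa."""


class MathStructureError(MathError):
    """Arity mismatch or malformed expression tree."""


class MathCycleError(MathError):
    """Recursive function definitions detected during inlining."""


class MathEvalError(MathError):
    """Runtime evaluation failure (e.g. exhausted piecewise)."""


class SIdLookupError(SbmlError, LookupError):
    """An SId that does not resolve in the model namespace."""

    def __init__(self, sid: str):
        self.sid = sid
        super().__init__(f"no element with id {sid!r}")


class ModelCompileError(SbmlError):
    """Model cannot be turned into an executable system."""


class UnsupportedModelError(SbmlError):
    """Model uses constructs outside the preconditions of a simulator."""


class SimulationError(SbmlError):
    """Numerical failure during simulation."""

    def __init__(self, message: str, last_time: float | None = None):
        self.last_time = last_time
        super().__init__(message)


class EventStormError(SimulationError):
    """More event firings than the runaway guard allows."""


class SolverError(SbmlError):
    """LP solver failure in flux balance analysis."""


class CapacityError(SbmlError):
    """Qualitative state space larger than the configured cap."""
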