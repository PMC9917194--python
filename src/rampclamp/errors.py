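"""Exception hierarchy.

Exit-code classes used by the CLI: 2 usage, 3 validation/format, 4 numerical.
"""


class RampClampError(Exception):
    """Base class for all package errors."""

    exit_code = 1


class UsageError(RampClampError):
    """Caller violated an operation's preconditions (bad arguments, bad query)."""

    exit_code = 2


class SelectionError(UsageError):
    """Malformed atom-selection expression; carries the offending position."""

    def __init__(self, message, position=None):
        super().__init__(message)
        self.position = position


class ConfigError(UsageError):
    """Invalid simulation/analysis configuration, detected before running."""


class ValidationError(RampClampError):
    """Data failed an invariant check (non-monotone times, occupancy outside [0,1], ...)."""

    exit_code = 3


class FormatError(ValidationError):
    """On-disk representation could not be parsed; carries a line number when known."""

    def __init__(self, message, line=None):
        super().__init__(message)
        self.line = line


class StructuralError(FormatError):
    """Trajectory structure inconsistent across models (atom-count mismatch etc.)."""


class NumericalError(RampClampError):
    """A fit or numerical procedure failed to converge or gave a non-physical result."""

    exit_code = 4

    def __init__(self, message, diagnostics=None):
        super().__init__(message)
        self.diagnostics = diagnostics
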