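"""Exception hierarchy with CLI exit codes.

Exit-code contract: 0 success, 2 validation/usage error, 3 computation
error, 4 configuration error.
"""


class ParacoexError(Exception):
    """Base class for all package errors."""

    exit_code = 1


class ValidationError(ParacoexError):
    """Input data violates the documented schema or referential integrity."""

    exit_code = 2


class UsageError(ParacoexError):
    """An operation was called with arguments outside its contract."""

    exit_code = 2


class ComputationError(ParacoexError):
    """A computation cannot proceed (empty group, degenerate input, non-convergence)."""

    exit_code = 3


class ConfigurationError(ParacoexError):
    """A run configuration is internally inconsistent or incomplete."""

    exit_code = 4
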