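"""Exception hierarchy.

Exit codes used by the command-line layer: 2 for configuration/usage
problems, 3 for unreadable or inconsistent input data, 4 for numerical
failures (singular systems, disconnected networks).
"""


class AflowError(Exception):
    """Base class for all package errors."""

    exit_code = 1


class ConfigError(AflowError):
    """Invalid run configuration (unknown key, bad value, unresolvable residue)."""

    exit_code = 2


class UsageError(AflowError):
    """A function was called with arguments that make no sense (API misuse)."""

    exit_code = 2


class InputError(AflowError):
    """Input data could not be read or is internally inconsistent."""

    exit_code = 3


class FormatError(InputError):
    """A structure/trajectory file violates its format."""


class TopologyMismatchError(InputError):
    """Frame atom count disagrees with the topology."""


class EmptyInputError(InputError):
    """A file or selection that must be nonempty is empty."""


class NumericalError(AflowError):
    """Linear-algebra failure (singular system, residual above tolerance)."""

    exit_code = 4


class ConnectivityError(NumericalError):
    """Sources and sinks do not share a connected component."""


class SpecError(UsageError):
    """A synthetic-system specification is internally inconsistent."""
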