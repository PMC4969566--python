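"""Exception hierarchy shared by the library and the CLI.

Each class carries the process exit code the CLI maps it to:
2 for input/format problems, 3 for invalid parameters, 4 for data
that is formally valid but degenerate for the requested analysis.
"""


class EegKappaError(Exception):
    """Base class for all errors raised by eegkappa."""

    exit_code = 1


class InputError(EegKappaError):
    """Unreadable, malformed or inconsistent input files."""

    exit_code = 2


class ParameterError(EegKappaError, ValueError):
    """A parameter violates an analysis precondition (e.g. delta_t = 1 s)."""

    exit_code = 3


class DegenerateDataError(EegKappaError):
    """Input is well-formed but carries no usable information.

    Examples: a constant segment where every instant is excluded from
    kappa estimation, or a constant density handed to the periodogram.
    """

    exit_code = 4
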