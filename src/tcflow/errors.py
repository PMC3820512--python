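"""Exception hierarchy shared across the package.

Exit-code mapping used by the CLI: input/configuration problems exit 2,
infeasible flow problems exit 3, internal invariant violations exit 4.
"""


class TcflowError(Exception):
    """Base class for all package errors."""

    exit_code = 4


class InputError(TcflowError):
    """Malformed input data (bad table, negative score, unknown type...)."""

    exit_code = 2


class ConfigError(TcflowError):
    """Invalid run configuration (missing time 0, windows not covering...)."""

    exit_code = 2


class InfeasibleError(TcflowError):
    """The flow problem cannot be built or solved (e.g. an empty stage)."""

    exit_code = 3


class InternalError(TcflowError):
    """An internal invariant failed (conservation violated beyond tolerance...)."""

    exit_code = 4
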