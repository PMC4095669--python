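"""Exception hierarchy shared by all coexnet modules.

Each error class carries the process exit code used by the command-line
front end (configuration problems exit 2, malformed data 3, empty results 4).
"""


class CoexnetError(Exception):
    """Base class for all coexnet errors."""

    exit_code = 1


class ConfigurationError(CoexnetError):
    """A parameter or configuration value violates its documented range."""

    exit_code = 2


class DataFormatError(CoexnetError):
    """An input file does not conform to its expected format."""

    exit_code = 3


class EmptyResultError(CoexnetError):
    """An operation produced an empty result where a non-empty one is required."""

    exit_code = 4


class DegenerateInputError(CoexnetError):
    """Numerically degenerate input (e.g. a constant expression vector)."""

    exit_code = 3
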