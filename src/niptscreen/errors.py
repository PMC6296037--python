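"""Exception hierarchy.

The CLI maps these onto distinct exit codes so that scripted pipelines can
tell an unreadable input apart from a statistically degenerate one.
"""


class NiptScreenError(Exception):
    """Base class for all package errors."""


class InputError(NiptScreenError):
    """Missing, unreadable or malformed input file."""


class ConfigError(NiptScreenError):
    """Invalid workflow configuration (detected before any compute)."""


class StatusMismatchError(NiptScreenError):
    """Samples or groups with incompatible correction status / geometry."""


class DegenerateInputError(NiptScreenError):
    """Input carries no usable signal (e.g. zero autosomal reads)."""


class DegenerateStatisticsError(NiptScreenError):
    """A statistic cannot be formed (zero SD, too few controls, ...)."""
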