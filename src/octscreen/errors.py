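"""Exception hierarchy shared across the package."""


class OCTScreenError(Exception):
    """Base class for all package-specific errors."""


class ParameterError(OCTScreenError, ValueError):
    """An argument violates a documented precondition (shape, sign, range)."""


class ConfigError(OCTScreenError, ValueError):
    """A screen configuration file is malformed or inconsistent."""


class UnsegmentableFrameError(OCTScreenError, RuntimeError):
    """A B-scan cannot be segmented (e.g. every column is saturated)."""


class UndefinedStatisticError(OCTScreenError, ValueError):
    """A statistic is undefined for the given inputs (e.g. Z' with equal means)."""
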