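"""Exception types shared across the pipeline."""


class PhenosyncError(Exception):
    """Base class for all package errors."""


class ConfigError(PhenosyncError, ValueError):
    """Invalid configuration value."""


class InputError(PhenosyncError, ValueError):
    """Invalid data passed to an operation (out-of-range reflectance, bad egg count, ...)."""


class NotEstimableError(PhenosyncError):
    """A curve fit was requested on too few points."""


class NoGreenUpError(PhenosyncError):
    """The fitted curve has no positive derivative in the evaluation window."""


class NotAssignableError(PhenosyncError):
    """A nestbox cannot be assigned a green-up value (no valid woodland neighbours)."""


class UndefinedStatisticError(PhenosyncError):
    """A statistic is undefined (zero variance, no qualifying pixels, ...)."""


class PipelineError(PhenosyncError):
    """A pipeline stage cannot run, e.g. because an upstream artifact is missing."""
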