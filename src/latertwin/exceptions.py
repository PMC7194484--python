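"""Exception hierarchy used across the package."""


class LatertwinError(Exception):
    """Base class for all package-specific errors."""


class MalformedInputError(LatertwinError):
    """Input violates a structural precondition (grid, shape, layout)."""


class UnusableRecordingError(LatertwinError):
    """A velocity recording cannot be processed (e.g. no detectable heartbeat)."""


class DegenerateDataError(LatertwinError):
    """A statistic is undefined on these data (zero variance, empty group)."""


class ConvergenceError(LatertwinError):
    """An optimiser failed to converge after restarts."""
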