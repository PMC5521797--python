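"""Typed errors raised across the estimation pipeline."""


class HeckcrashError(Exception):
    """Base class for all package errors."""


class InvalidInputError(HeckcrashError, ValueError):
    """Malformed or out-of-domain data (negative counts, non-binary flags, ...)."""


class ConfigError(HeckcrashError, ValueError):
    """Inconsistent configuration (unknown column, dimension mismatch, ...)."""


class CollinearityError(HeckcrashError):
    """Design matrix is rank deficient."""


class SeparationError(HeckcrashError):
    """Probit outcome is (quasi-)completely separated; estimates diverge."""


class ConvergenceError(HeckcrashError):
    """Optimizer failed to converge within the iteration budget.

    Carries the last iterate so callers can inspect it.
    """

    def __init__(self, message, last_iterate=None):
        super().__init__(message)
        self.last_iterate = last_iterate
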