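"""Exception hierarchy used across the package."""


class CbalError(Exception):
    """Base class for package errors."""


class ValidationError(CbalError, ValueError):
    """An argument violates a documented precondition."""


class SingleClassError(CbalError):
    """A labeled set contains only one class where both are required."""


class ExhaustionError(CbalError):
    """A query ran out of candidates before its class quotas were filled.

    Carries the partially filled batch so callers can inspect what was
    obtained before exhaustion.
    """

    def __init__(self, message, partial=None, n_annotated=0):
        super().__init__(message)
        self.partial = partial
        self.n_annotated = n_annotated


class UndefinedProbabilityError(CbalError):
    """The prevalence update is undefined (no samples remain in the pool)."""


class ModelInconsistencyError(CbalError):
    """A cost-model update produced a probability outside [0, 1]."""
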