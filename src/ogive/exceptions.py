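"""Package-specific error types.

These distinguish statistical degeneracies (which a caller may want to
catch and report) from plain argument errors.
"""


class OgiveError(Exception):
    """Base class for all package-specific errors."""


class DegenerateDesignError(OgiveError, ValueError):
    """The item-regression design x = [theta, -1] is singular.

    Raised when all person traits are identical, so x'x has rank 1 and the
    bivariate item conditional is undefined.
    """


class TailMassError(OgiveError, ValueError):
    """A truncation interval carries no double-precision-representable mass."""


class TruncationStallError(OgiveError, RuntimeError):
    """Rejection sampling for a positive-slope draw exhausted its budget."""

    def __init__(self, item: int, max_rejects: int, acceptance_estimate: float):
        self.item = item
        self.max_rejects = max_rejects
        self.acceptance_estimate = acceptance_estimate
        super().__init__(
            f"item {item}: slope-positivity rejection sampling exhausted "
            f"{max_rejects} proposals (estimated acceptance probability "
            f"{acceptance_estimate:.3e})"
        )


class ChainAborted(OgiveError, RuntimeError):
    """A Gibbs chain stopped before completing its configured iterations.

    ``partial`` holds whatever samples were collected before the failure;
    they are flagged unusable and should not be summarized.
    """

    def __init__(self, message: str, partial=None):
        self.partial = partial
        super().__init__(message)
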