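"""Exception hierarchy shared by all pipeline stages.

Every error raised on invalid data or parameters derives from
:class:`StrengthLabError` so callers can distinguish pipeline failures
from programming errors.
"""


class StrengthLabError(Exception):
    """Base class for all pipeline errors."""


class InvalidParameterError(StrengthLabError, ValueError):
    """A parameter violates its documented precondition (e.g. Nyquist)."""


class TooShortError(StrengthLabError, ValueError):
    """The signal is too short for the requested operation."""


class NoOnsetError(StrengthLabError):
    """No contraction/activation onset could be located in the trace."""


class SuspiciousBaselineError(StrengthLabError):
    """The trigger fell inside the presumed pre-contraction baseline."""


class InsufficientBaselineError(StrengthLabError):
    """Not enough pre-onset samples for the baseline regression."""


class TruncatedTrialError(StrengthLabError):
    """The trace ends before the analysis window does."""


class AllRejectedError(StrengthLabError):
    """Every explosive attempt was screened out.

    Carries a tally of rejection reasons in :attr:`tally`.
    """

    def __init__(self, tally):
        self.tally = dict(tally)
        super().__init__(f"all attempts rejected: {self.tally}")


class NormalizationError(StrengthLabError, ValueError):
    """A normalizer (e.g. MVC EMG amplitude) is zero or negative."""


class NotQuietError(StrengthLabError):
    """The presumed quiet-stance window is not stationary."""


class NoTakeoffError(StrengthLabError):
    """Ground reaction force never drops below the take-off threshold."""


class DegeneratePhaseError(StrengthLabError):
    """A movement phase is too short to average meaningfully."""


class InvalidProfileError(StrengthLabError):
    """A force-velocity or load-velocity fit has a non-physical slope."""


class ImbalanceError(StrengthLabError):
    """The factorial design has missing cells, so classical ANOVA
    sums of squares cannot be partitioned."""


class ManifestError(StrengthLabError):
    """A study directory or manifest file is malformed or missing."""
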