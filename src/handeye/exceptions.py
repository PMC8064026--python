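"""Exception hierarchy for the hand-eye analysis pipeline.

Every anticipated failure mode raises a subclass of :class:`HandEyeError`,
so callers (notably the batch pipeline, which must skip bad trials rather
than abort) can catch one base class.
"""


class HandEyeError(Exception):
    """Base class for all package errors."""


class ConfigurationError(HandEyeError, ValueError):
    """An invalid parameter or generator configuration."""


class SeriesError(HandEyeError, ValueError):
    """A malformed or too-short time series."""


class NoGraspError(HandEyeError):
    """Grip force never exceeded the grasp threshold."""


class NoReachError(HandEyeError):
    """Hand speed never met the reach-onset criterion before grasp."""


class LiftDetectionError(HandEyeError):
    """Object never moved, or never re-stabilised, after grasp onset."""


class AllInvalidError(SeriesError):
    """Every sample in the analysed segment is flagged invalid."""


class TrialInvalidError(HandEyeError):
    """Trial unusable for coupling (e.g. segment below minimum overlap)."""


class UndefinedCorrelationError(HandEyeError):
    """Cross-correlation undefined (constant signal on every overlap)."""


class StatsError(HandEyeError, ValueError):
    """Invalid input to a statistical routine."""
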