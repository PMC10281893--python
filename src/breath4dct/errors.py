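"""Exception hierarchy.

Every error raised on purpose by this package derives from
:class:`Breath4DCTError` so callers can catch the package's failures
without swallowing programming errors.
"""


class Breath4DCTError(Exception):
    """Base class for all breath4dct errors."""


class MalformedInputError(Breath4DCTError):
    """Input data violates a structural requirement (e.g. non-uniform sampling)."""


class FormatError(Breath4DCTError):
    """A file could not be interpreted under the given dialect."""


class MissingChannelError(Breath4DCTError):
    """A required channel (e.g. beam-on flags) is absent."""


class EmptyWindowError(Breath4DCTError):
    """No beam-on sample exists, so no scan window can be defined."""


class DegenerateFitError(Breath4DCTError):
    """A regression fit is undefined (e.g. constant time vector)."""


class ZeroRangeError(Breath4DCTError):
    """Normalization of a constant signal is undefined."""


class InsufficientCyclesError(Breath4DCTError):
    """Fewer breathing cycles than the operation requires."""


class DegenerateSpecError(Breath4DCTError):
    """A synthetic-signal specification cannot produce a valid signal."""


class IntervalRangeError(Breath4DCTError):
    """An interval lies outside the signal's time support."""


class SizeError(Breath4DCTError):
    """A cohort or pool is too small for the requested selection/matching."""


class InsufficientSignalError(Breath4DCTError):
    """The breathing trace is too short for the simulated scan."""


class LearningError(Breath4DCTError):
    """Too few pre-scan cycles to learn a reference cycle."""


class EmptyResultError(Breath4DCTError):
    """An acquisition result carries no coverage data."""


class UndefinedCorrelationError(Breath4DCTError):
    """Correlation of a constant sample is undefined."""


class ValidationError(Breath4DCTError):
    """A value falls outside its documented domain."""
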