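"""Exception hierarchy for the zfcardio pipeline.

All package-specific failures derive from :class:`ZfcardioError` so callers
can catch pipeline problems without masking programming errors.
"""


class ZfcardioError(Exception):
    """Base class for all zfcardio errors."""


class FormatError(ZfcardioError):
    """A tracking table does not follow the expected layout (e.g. wrong
    body-part set, missing coordinate columns)."""


class TableParseError(FormatError):
    """A cell in a tracking table could not be parsed as a number."""


class ContractViolation(ZfcardioError):
    """Input data violates a documented precondition (e.g. non-finite
    coordinates reaching the geometry stage)."""


class UnrecoverableTrackError(ZfcardioError):
    """A landmark is confident in zero frames, so no gap-filling strategy
    can reconstruct its trajectory."""


class InsufficientBeatsError(ZfcardioError):
    """Too few cardiac cycles were found to compute the requested quantity."""


class InvertedCycleError(ZfcardioError):
    """A cardiac cycle has end-systolic volume >= end-diastolic volume."""


class ParameterError(ZfcardioError, ValueError):
    """A user-supplied parameter is outside its documented range."""


class DomainError(ZfcardioError, ValueError):
    """A numeric argument is outside the mathematical domain of an
    operation (e.g. non-positive axis length)."""
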