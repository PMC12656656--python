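"""Exception hierarchy for ctdoseiq.

All package-specific failures derive from :class:`CtDoseIqError` so callers
can catch one base class; subclasses keep stage-specific semantics.
"""


class CtDoseIqError(Exception):
    """Base class for all ctdoseiq errors."""


class GeometryError(CtDoseIqError):
    """Phantom/brain layout does not fit or structures overlap."""


class DomainError(CtDoseIqError, ValueError):
    """A physical parameter is outside its valid domain (e.g. dose <= 0)."""


class RoiPlacementError(CtDoseIqError):
    """ROI extends outside the image or encloses too few pixels."""


class AggregationError(CtDoseIqError):
    """ROI statistics with mismatched tissue labels cannot be pooled."""


class UndefinedCnrError(CtDoseIqError, ZeroDivisionError):
    """CNR denominator (reference-region SD) is zero."""


class FitError(CtDoseIqError):
    """Too few usable points for a regression fit."""


class NoSolutionError(CtDoseIqError):
    """A threshold equation has no root in the admissible range."""


class NarrowDoseRangeError(CtDoseIqError):
    """Dose range too narrow (< factor 2) for a meaningful power-law trend."""


class DicomTagError(CtDoseIqError, KeyError):
    """A required DICOM tag is missing; the message names the tag."""
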