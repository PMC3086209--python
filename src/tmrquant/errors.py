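"""Exception hierarchy for tmrquant.

All domain errors derive from :class:`TmrError` so callers can catch one
base class; specific subclasses mark which stage of the measurement chain
failed.
"""


class TmrError(Exception):
    """Base class for all tmrquant domain errors."""


class ValidationError(TmrError, ValueError):
    """An input violates a documented precondition or invariant."""


class UnsupportedFormatError(TmrError):
    """A file is readable but not in a supported format (e.g. RGB TIFF)."""


class SchemaError(TmrError):
    """Tabular/JSON input is missing required columns or keys."""


class DegenerateNormalizationError(TmrError):
    """Two-point normalization anchors have equal means."""


class PolarityError(TmrError):
    """Background reads brighter than sound tissue (or a fitted edge slope
    is non-positive): the film polarity or window placement is wrong."""


class AlignmentError(TmrError):
    """Grid-peak registration could not find a consistent offset."""


class NoCrossingError(TmrError):
    """A profile never crosses the requested density level."""


class InsufficientDataError(TmrError):
    """Too few samples/steps to perform a fit."""


class RegistrationFaultError(TmrError):
    """Measured geometry is inconsistent beyond tolerance (e.g. the after
    surface lies outside the before surface)."""
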