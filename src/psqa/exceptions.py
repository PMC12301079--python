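"""Exception hierarchy for the psqa package."""


class PsqaError(Exception):
    """Base class for all package errors."""


class FormatError(PsqaError):
    """A file could not be parsed; the message names the offending field."""


class ValidationError(PsqaError):
    """A domain object violates one of its invariants."""


class OutOfBoundsError(PsqaError):
    """A reference point lies outside the searchable region of the evaluated grid."""


class NormalizationError(PsqaError):
    """The gamma normalization dose is zero or undefined."""


class EmptyAnalysisError(PsqaError):
    """No reference point survives the low-dose threshold (distinct from GPR = 0)."""


class DegenerateLabelsError(PsqaError):
    """ROC analysis requested on a cohort with only one ground-truth class."""


class UndefinedCorrelationError(PsqaError):
    """Correlation requested on a constant input vector."""


class ClosedApertureError(PsqaError):
    """Aperture metric requested on a fully closed control point."""
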