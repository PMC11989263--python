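"""Exception hierarchy for the pipeline.

Errors are split by provenance: malformed input files raise
:class:`FormatError`, inputs that parse but violate a domain invariant raise
:class:`ValidationError`, and statistical procedures that cannot run on the
supplied design raise :class:`AnalysisError` subclasses.
"""


class SoyhapError(Exception):
    """Base class for all package errors."""


class FormatError(SoyhapError):
    """A file could not be parsed under its declared format."""


class ValidationError(SoyhapError):
    """Parsed data violates a domain invariant (e.g. CDS length not a
    multiple of three, R1 recorded before VE)."""


class AnalysisError(SoyhapError):
    """A statistical operation cannot run on the supplied data."""


class DegenerateDesignError(AnalysisError):
    """Regression/ANOVA design with no usable variation."""


class InsufficientDataError(AnalysisError):
    """Fewer observations than the procedure requires."""


class UnsupportedVariantError(SoyhapError):
    """A variant whose CDS effect cannot be resolved (e.g. a deletion
    spanning an exon boundary); reported rather than guessed."""
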