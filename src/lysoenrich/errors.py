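"""Exception hierarchy shared across the pipeline.

Every stage raises a subclass of :class:`LysoEnrichError` so callers can
distinguish pipeline failures from programming errors; messages always name
the offending entity (column, row, replicate, protein).
"""


class LysoEnrichError(Exception):
    """Base class for all pipeline errors."""


class FormatError(LysoEnrichError):
    """A required column or structural feature is missing from an input table."""


class ParseError(LysoEnrichError):
    """A cell could not be converted to the expected type; names the row."""


class DesignError(LysoEnrichError):
    """The study design is inconsistent (duplicate replicate, unknown channel,
    or a quantification referencing a (cell_line, replicate) not in the design)."""


class VocabularyError(LysoEnrichError):
    """An annotation uses a token outside the declared closed vocabulary."""


class CatalogError(LysoEnrichError):
    """An annotation catalog row violates a catalog invariant."""


class DegenerateInputError(LysoEnrichError):
    """Input is too small or too uniform for the requested estimation."""


class ReferenceSetError(LysoEnrichError):
    """No qualifying reference subunit in a replicate; names the replicate."""


class ComparisonError(LysoEnrichError):
    """Two profiles share no proteins, so no comparison is possible."""


class ConsistencyError(LysoEnrichError):
    """Cross-table invariant broken (e.g. enriched proteins not a subset of
    identified proteins)."""


class ConfigError(LysoEnrichError):
    """A configuration value is out of range or internally inconsistent."""
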