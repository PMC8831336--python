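"""Exception hierarchy.

Every reader rejects malformed input instead of coercing it, and every stage
raises a stage-specific error so pipeline failures name their origin.
"""


class PhaseBmdError(Exception):
    """Base class for all package errors."""


class FormatError(PhaseBmdError, ValueError):
    """On-disk artifact does not parse or violates its format contract."""


class ValidationError(PhaseBmdError, ValueError):
    """In-memory object violates a schema or invariant."""


class GeometryError(PhaseBmdError, ValueError):
    """Volume geometry (spacing, affine, field of view) is unusable."""


class NormalizationError(PhaseBmdError, ValueError):
    """Intensity normalization impossible (e.g. zero variance)."""


class CoverageError(PhaseBmdError, ValueError):
    """No usable vertebral levels / slices / includable vertebrae remain."""


class AggregationError(PhaseBmdError, ValueError):
    """Slice-level predictions cannot be aggregated (empty input)."""


class ExtractionError(PhaseBmdError, ValueError):
    """A mask region needed for BMD extraction is empty or missing."""


class FitError(PhaseBmdError, ValueError):
    """Correction-model fit impossible (too few or degenerate pairs)."""


class CorrectionError(PhaseBmdError, ValueError):
    """No correction model available for a contrast-enhanced phase."""


class ConfigError(PhaseBmdError, ValueError):
    """Configuration value outside its contract."""


class StatisticsError(PhaseBmdError, ValueError):
    """Statistical computation impossible (e.g. fewer than 2 pairs)."""
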