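"""Exception hierarchy for filmspec."""


class FilmspecError(Exception):
    """Base class for all filmspec errors."""


class InvalidAxisError(FilmspecError):
    """Wavenumber axis violates its invariants (span, spacing, frame count)."""


class MetadataError(FilmspecError):
    """A stored stack is missing required axis/provenance metadata."""


class FormatError(FilmspecError):
    """On-disk layout is inconsistent (e.g. page count vs. axis length)."""


class EmptySelectionError(FilmspecError):
    """A pixel/bin selection is empty where at least one element is required."""


class ConfigError(FilmspecError):
    """A configuration value is out of its allowed set."""


class NormalizationError(FilmspecError):
    """Spectrum cannot be normalized (zero or negative area / norm)."""


class SaturationError(FilmspecError):
    """A physical response left its valid range (e.g. >100 % quench)."""
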