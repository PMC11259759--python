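"""Exception hierarchy.

``ValidationError`` covers malformed user input (exit code 1 in the CLI);
everything else inheriting from :class:`PolyreactError` maps to a runtime
failure (exit code 2).
"""


class PolyreactError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(PolyreactError, ValueError):
    """Malformed input: bad residues, out-of-range values, unknown codes."""


class SchemaError(ValidationError):
    """Tabular input is missing required columns."""


class UnsupportedFormatError(PolyreactError):
    """Antibody layout outside the supported envelope (e.g. >4 domains)."""


class ExtractionError(PolyreactError):
    """Variable-domain extraction found no domain on a chain."""


class LengthError(PolyreactError):
    """A sequence exceeds the configured capacity of the encoder/embedder."""


class ShapeError(PolyreactError):
    """Tensor shape mismatch between configuration and data."""


class DependencyError(PolyreactError):
    """An optional external dependency is required but not installed."""
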