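"""Exception hierarchy shared across the pipeline stages."""


class CappscanError(Exception):
    """Base class for all package errors."""


class FeatureTableParseError(CappscanError):
    """A feature-table or GFF3 line could not be parsed; carries the line number."""

    def __init__(self, path, line_no, message):
        self.path = str(path)
        self.line_no = line_no
        super().__init__(f"{path}:{line_no}: {message}")


class FocalLookupError(CappscanError, LookupError):
    """The requested focal accession is absent (or ambiguous) in the annotation."""


class SizingError(CappscanError, ValueError):
    """A contig is too small to host the requested operon template."""


class VocabularyError(CappscanError, ValueError):
    """A domain label outside the controlled vocabulary was supplied."""


class IncomputableDistanceError(CappscanError, ValueError):
    """No comparable alignment columns between a pair of rows."""

    def __init__(self, message, pair=None):
        self.pair = pair
        super().__init__(message)


class SaturationError(CappscanError, ValueError):
    """p-distance at or beyond the Kimura correction's domain boundary."""

    def __init__(self, message, pair=None, p=None):
        self.pair = pair
        self.p = p
        super().__init__(message)


class NewickParseError(CappscanError, ValueError):
    """Malformed Newick input."""


class ConfigError(CappscanError, ValueError):
    """Invalid or incomplete pipeline configuration."""
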