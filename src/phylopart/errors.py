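"""Exception hierarchy shared across the pipeline.

Every error raised by a pipeline stage derives from :class:`PhylopartError`
so the CLI can catch one type, label the failing stage and exit non-zero.
"""


class PhylopartError(Exception):
    """Base class for all package errors."""


class AlignmentError(PhylopartError):
    """Ragged or otherwise structurally invalid alignment."""


class ParseError(PhylopartError):
    """Illegal symbol or unparseable record; message names id and column."""


class MetadataError(PhylopartError):
    """Inconsistent sample metadata (duplicate ids, ambiguous locality)."""


class DataError(PhylopartError):
    """Valid inputs that cannot support the requested computation."""


class ConfigError(PhylopartError):
    """Invalid configuration value."""
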