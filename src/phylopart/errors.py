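"""Exception hierarchy.

Every error raised by this package derives from :class:`PhylopartError`,
so pipeline drivers can record per-dataset failures without aborting a
collection run.
"""


class PhylopartError(Exception):
    """Base class for all phylopart errors."""


class ParseError(PhylopartError):
    """A file could not be parsed; carries the offending line number."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class ValidationError(PhylopartError):
    """Structurally parseable input that violates an invariant."""


class TreeMismatchError(PhylopartError):
    """Leaf sets of a tree and a matrix (or two trees) do not line up."""


class DegeneratePartitionError(PhylopartError):
    """A partition retains no parsimony-informative characters."""


class CoverageError(PhylopartError):
    """Too few taxa shared between a matrix and its reference tree."""


class UninformativeCharacterError(PhylopartError):
    """Retention index requested for a character with g == m."""


class ConfigError(PhylopartError):
    """Invalid run or search configuration."""
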