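"""Exception hierarchy for snopair.

Every error raised on bad user input derives from :class:`SnopairError` so the
CLI can map them onto a data-validation exit code.
"""


class SnopairError(Exception):
    """Base class for all snopair errors."""


class InvalidResidueError(SnopairError):
    """A character outside the 21-letter alphabet (20 amino acids + pad)."""


class NotACysteineError(SnopairError):
    """A site position whose residue is not 'C'."""


class PositionOutOfRangeError(SnopairError):
    """A 1-based position outside the parent sequence."""


class InconsistentAnnotationError(SnopairError):
    """A site annotation that does not match the protein it names."""


class EmptyDatasetError(SnopairError):
    """An operation that needs at least one window received none."""


class IncompatibleMatricesError(SnopairError):
    """Two pair matrices with mismatched gap or shape."""


class DimensionMismatchError(SnopairError):
    """Vector/matrix/window dimensions that do not line up."""


class UndefinedMetricsError(SnopairError):
    """Metrics requested on an empty confusion table."""


class InfeasibleFoldError(SnopairError):
    """A class with fewer members than the requested fold count."""


class LeakageError(SnopairError):
    """Train/test overlap detected when disjointness was requested."""


class PeptideTableError(SnopairError):
    """A malformed peptide-table row; message carries file and line."""


class ModelFormatError(SnopairError):
    """A corrupted or version-incompatible model file."""


class ConfigError(SnopairError):
    """An invalid configuration value."""
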