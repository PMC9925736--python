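"""Exception hierarchy.

Every error the pipeline can raise derives from :class:`PorcimetryError`, so
callers (and the CLI) can distinguish pipeline failures from programming
errors.  Parameter-validation errors also derive from :class:`ValueError`.
"""


class PorcimetryError(Exception):
    """Base class for all errors raised by this package."""


class InvalidParameterError(PorcimetryError, ValueError):
    """A parameter violates its documented precondition."""


class DegenerateGeometryError(PorcimetryError):
    """Input geometry does not determine the requested fit (collinear points,
    fewer than three recoverable cube faces, ...)."""


class NoPlaneFoundError(PorcimetryError):
    """RANSAC found no plane reaching the required inlier fraction."""


class InsufficientDataError(PorcimetryError):
    """Too few points to carry out a measurement."""


class WithersNotFoundError(PorcimetryError):
    """The dorsal height profile has fewer than two local maxima."""


class InsufficientCoverageError(PorcimetryError):
    """Angular coverage of a polar slice is below the minimum for a closed fit."""


class TrainingDivergedError(PorcimetryError):
    """Training loss became non-finite."""


class InvalidRecordError(PorcimetryError, ValueError):
    """A tabular record violates its invariants (e.g. determination before birth)."""


class ImputationError(PorcimetryError):
    """Imputation is impossible (e.g. every height is missing)."""


class NormalizationError(PorcimetryError):
    """A row cannot be normalized (zero Euclidean norm)."""


class UndefinedCorrelationError(PorcimetryError):
    """Pearson correlation is undefined because a column is constant."""
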