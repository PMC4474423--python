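"""Exception hierarchy shared across the package.

All data-quality and numerical failures raise subclasses of :class:`ComreError`
so callers (including the CLI) can distinguish them from programming errors.
"""


class ComreError(Exception):
    """Base class for all errors raised by this package."""


class ExpressionParseError(ComreError, ValueError):
    """A delimited expression file could not be parsed (non-numeric or
    missing cell, duplicate identifiers). The message names the offending
    row/column."""


class ProbeMapError(ComreError, ValueError):
    """A probe-to-gene mapping table is invalid or incomplete."""


class ZeroVarianceError(ComreError, ValueError):
    """A vector that must be z-transformed has zero standard deviation
    (or, for coefficient-of-variation selection, zero mean)."""


class MissingGeneError(ComreError, KeyError):
    """A requested gene/modulator identifier is absent from the matrix."""


class RankDeficientError(ComreError, ValueError):
    """The regression design matrix is (numerically) rank deficient; the
    message names the collinear columns."""
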