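"""Exception hierarchy for lattice-trial analysis.

All errors raised by the package derive from :class:`LattiqError` so callers
can catch one base class at pipeline level while tests can assert on the
specific failure mode.
"""


class LattiqError(Exception):
    """Base class for all package errors."""


class DesignError(LattiqError):
    """Invalid or inconsistent lattice design specification."""


class ModelError(LattiqError):
    """Invalid simulation model (dimension mismatch, non-PSD correlation)."""


class SchemaError(LattiqError):
    """Malformed plot-level input table (missing column, duplicates, ...)."""


class BalanceError(LattiqError):
    """Plot table is incomplete: some (accession, replication) cells missing."""


class DegenerateDesignError(LattiqError):
    """ANOVA has no residual degrees of freedom."""


class SelectionError(LattiqError):
    """No predictor trait qualifies for the path model."""


class SingularityError(LattiqError):
    """Predictor correlation matrix is numerically singular."""


class StandardizationError(LattiqError):
    """A trait has zero spread and cannot be z-scored."""
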