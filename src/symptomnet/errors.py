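"""Exception hierarchy for symptomnet.

All package-specific failures derive from :class:`SymptomNetError` so callers
can catch one base class; each subclass also derives from the closest builtin
(ValueError / KeyError) for idiomatic handling.
"""


class SymptomNetError(Exception):
    """Base class for all symptomnet errors."""


class InvalidMarginalError(SymptomNetError, ValueError):
    """Category probabilities are negative or do not sum to one."""


class InfeasibleMarginalError(SymptomNetError, ValueError):
    """A prevalence/severity pair no 4-category distribution can satisfy."""


class InvalidDesignError(SymptomNetError, ValueError):
    """A planted-hub design with hub correlation <= background correlation."""


class NotPositiveSemidefiniteError(SymptomNetError, ValueError):
    """A latent correlation matrix with negative eigenvalues, repair disabled."""


class MissingItemError(SymptomNetError, KeyError):
    """An item or node id not present in the matrix/network."""


class InvalidConfigError(SymptomNetError, ValueError):
    """Instrument configuration violating its structural invariants."""


class EmptyDatasetError(SymptomNetError, ValueError):
    """No complete records remain after listwise deletion."""


class InsufficientDataError(SymptomNetError, ValueError):
    """Too few participants (or items) for the requested statistic."""


class UndefinedAlphaError(SymptomNetError, ValueError):
    """Cronbach's alpha requested for a composite with zero total variance."""


class UndefinedCorrelationError(SymptomNetError, ValueError):
    """Rank correlation requested for a constant vector."""


class SchemaError(SymptomNetError, ValueError):
    """Response CSV columns do not match the instrument configuration."""


class ResponseValidationError(SymptomNetError, ValueError):
    """A response cell outside the admissible score set {0, 1, 2, 3}."""
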