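"""Exception hierarchy shared by all herbnet modules."""


class HerbnetError(Exception):
    """Base class for all herbnet errors."""


class SchemaError(HerbnetError):
    """A mandatory column is missing or a column has the wrong type."""


class ValidationError(HerbnetError):
    """Row-level content violates a table or network invariant."""


class InsufficientDataError(HerbnetError):
    """Too few usable observations for a statistical comparison."""


class DimensionError(HerbnetError):
    """Vector operands have incompatible lengths."""


class UndefinedSimilarityError(HerbnetError):
    """Similarity is undefined (e.g. both descriptor vectors are zero)."""


class UndefinedFractionError(HerbnetError):
    """A fraction with zero denominator was requested."""


class UndefinedKappaError(HerbnetError):
    """Cohen's kappa is undefined because expected agreement equals 1."""


class EmptyQueryError(HerbnetError):
    """The query gene list is empty after normalization."""


class IncompleteDesignError(HerbnetError):
    """A factorial cell is missing from a full-factorial design."""


class UnbalancedDesignError(HerbnetError):
    """Replicate counts differ across factorial cells."""


class ConfigError(HerbnetError):
    """Invalid synthetic-data generator configuration."""
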