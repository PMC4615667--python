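"""Exception hierarchy for the nodqol pipeline."""


class NodqolError(Exception):
    """Base class for all nodqol errors."""


class SchemaError(NodqolError):
    """An input table is missing a required column or has an unusable layout."""


class InsufficientDataError(NodqolError):
    """Too few persons or strata to carry out the requested estimation."""


class ConfigurationError(NodqolError):
    """A threshold or simulation setting is infeasible for the data at hand."""


class UndefinedCorrelationError(NodqolError):
    """Pearson correlation requested for a constant (zero-variance) input."""


class DomainError(NodqolError):
    """Data outside the mathematical domain of the requested model (e.g. log of a
    non-positive stratum mean)."""


class EmptyWeightTableError(NodqolError):
    """No diagnosis code satisfies the sole-diagnosis count requirement."""
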