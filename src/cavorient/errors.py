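"""Exception hierarchy shared across the package."""


class CavorientError(Exception):
    """Base class for all package-specific errors."""


class SchemaError(CavorientError):
    """A required column is missing or an enum value is unknown."""


class ValueRangeError(CavorientError):
    """A field value falls outside its permitted range."""


class ConsistencyError(CavorientError):
    """Cross-field invariant violated (e.g. a nest flagged on a start)."""


class DuplicateError(CavorientError):
    """A record that must be unique appears more than once."""


class EmptyInputError(CavorientError):
    """An operation received no data."""


class InsufficientDataError(CavorientError):
    """Too few observations for the requested statistic."""


class WraparoundError(CavorientError):
    """Angles span an arc too wide for a linear treatment."""


class ConvergenceError(CavorientError):
    """A model fit failed to converge."""


class ModelSpecError(CavorientError):
    """An inconsistent model specification was requested."""
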