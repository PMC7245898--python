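"""Exception hierarchy for the package.

Every error raised on purpose by levocea derives from :class:`LevoceaError`,
so callers can catch one type at the CLI boundary.
"""


class LevoceaError(Exception):
    """Base class for all levocea errors."""


class SchemaError(LevoceaError):
    """A cohort file does not match the documented column schema."""


class ParseError(LevoceaError):
    """A cohort row holds a value that cannot be interpreted."""


class ConsistencyError(LevoceaError):
    """A record violates a clinical invariant (e.g. shock without LCO)."""


class DegenerateTableError(LevoceaError):
    """A contingency table has a zero marginal where the test needs one."""


class UndefinedProportionError(LevoceaError):
    """A percentage was requested for an empty arm."""


class InsufficientDataError(LevoceaError):
    """Too few observations for the requested test."""


class ValidationError(LevoceaError):
    """A config value is outside its admissible range."""


class LookupError_(LevoceaError):
    """A resource code is missing from the cost catalogue."""


class EstimationError(LevoceaError):
    """Probabilities were requested from an empty arm."""


class ConservationError(LevoceaError):
    """Pathway probabilities do not sum to one."""


class ConfigurationError(LevoceaError):
    """A config file is missing a required block or parameter."""
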