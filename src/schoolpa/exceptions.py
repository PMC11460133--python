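"""Exception hierarchy for schoolpa."""


class SchoolPAError(Exception):
    """Base class for all package errors."""


class ConfigurationError(SchoolPAError):
    """Invalid configuration value; the message names the offending field."""


class SchemaError(SchoolPAError):
    """A referenced variable or column is absent from the data schema."""


class MarginInfeasibleError(SchoolPAError):
    """A raking margin category has no participant with positive weight."""


class MarginConsistencyError(SchoolPAError):
    """Raking margins do not share a common grand total."""


class DegenerateDesignError(SchoolPAError):
    """The survey design cannot support variance estimation (e.g. one PSU)."""


class EmptyDomainError(SchoolPAError):
    """An estimator was called on an empty domain."""


class EffectSpecError(SchoolPAError):
    """An intervention effect specification references an unknown determinant
    or carries an invalid value."""


class DataCoverageError(SchoolPAError):
    """A CPI or PPP lookup is missing for a required (currency, year)."""
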