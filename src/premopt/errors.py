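"""Exception hierarchy shared across the package."""


class PremoptError(Exception):
    """Base class for all package errors."""


class SchemaError(PremoptError):
    """A column or variable does not match the codebook / expected schema."""


class ValidationError(PremoptError):
    """A cell value violates the response-scale or demographic constraints."""


class ConfigurationError(PremoptError):
    """A scenario or pipeline configuration is invalid."""


class DomainError(PremoptError):
    """An argument is outside the mathematical domain of an operation."""


class FitError(PremoptError):
    """Model estimation cannot proceed (e.g. an empty outcome category)."""
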