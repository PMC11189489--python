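"""Exception hierarchy shared across the package."""


class DepotPKError(Exception):
    """Base class for all package-specific errors."""


class DomainError(DepotPKError, ValueError):
    """A numeric argument is outside its physically meaningful domain."""


class ConfigurationError(DepotPKError, ValueError):
    """A design/parameter object is internally inconsistent or incomplete."""


class SchemaError(DepotPKError, ValueError):
    """Tabular input does not match the declared CSV schema."""


class EstimationError(DepotPKError, RuntimeError):
    """A fit cannot be performed (too few usable points, all records rejected)."""


class AnalysisError(DepotPKError, RuntimeError):
    """A downstream analysis request is incompatible with the supplied data."""
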