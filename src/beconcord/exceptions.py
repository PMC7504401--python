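"""Exception hierarchy shared across the package."""


class BeconcordError(Exception):
    """Base class for all package-specific errors."""


class DimensionError(BeconcordError, ValueError):
    """Inconsistent array/table dimensions in a simulation spec or dataset."""


class ConfigurationError(BeconcordError, ValueError):
    """Invalid configuration (missing reference condition, bad thresholds, ...)."""


class GroupingError(BeconcordError, ValueError):
    """A two-group operation was asked of data without two usable groups."""


class DegenerateVarianceError(BeconcordError, ValueError):
    """All residual variances are zero; the variance prior cannot be fitted."""


class DomainError(BeconcordError, ValueError):
    """A numeric input lies outside its mathematical domain (e.g. p not in [0,1])."""


class ReferenceIntegrityError(BeconcordError, ValueError):
    """A reference gene is undetected in a sample required for normalization."""


class InsufficientReplicationError(BeconcordError, ValueError):
    """A compared condition has fewer than two usable samples."""


class IntegrityError(BeconcordError, ValueError):
    """Conflicting duplicate records (e.g. two different calls for one gene/system)."""


class ParseError(BeconcordError, ValueError):
    """A delimited input file violates its format contract."""
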