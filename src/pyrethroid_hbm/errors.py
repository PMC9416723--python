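"""Exception hierarchy shared across the package."""


class HbmError(Exception):
    """Base class for all package errors."""


class RegistryLoadError(HbmError):
    """A registry file failed schema validation (names file, row and field)."""


class IntegrityError(HbmError):
    """A cross-reference inside the registry does not resolve."""


class RegistryLookupError(HbmError, KeyError):
    """An id passed to a registry query does not exist."""


class PolicyError(HbmError):
    """A derivation was requested for a substance flagged non-assessable."""


class DomainError(HbmError, ValueError):
    """A numeric argument is outside the mathematical domain of an operation."""


class ExposureValidationError(HbmError):
    """An exposure table violated the schema or a percentile invariant."""


class PercentileSumError(HbmError):
    """Percentiles of a sum were requested without a reported sum percentile."""


class AllocationError(HbmError):
    """A biomarker-to-substance allocation names a substance without a result."""


class ConsistencyError(HbmError):
    """Mixture contributions exceed the measured common-metabolite level."""


class FitError(HbmError):
    """Quantile fitting failed (non-monotone input or optimizer failure)."""
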