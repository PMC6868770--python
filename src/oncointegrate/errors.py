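"""Exception types shared across the package."""


class OncoIntegrateError(Exception):
    """Base class for all package errors."""


class DelimiterError(OncoIntegrateError):
    """No delimiter candidate splits the file consistently."""


class MissingAttributeHeaderError(OncoIntegrateError):
    """A file has no attribute (column-name) row."""


class SchemaViolationError(OncoIntegrateError):
    """A record violates the mandatory data schema (ID / Sample ID)."""


class StoreFormatError(OncoIntegrateError):
    """A document-store file contains a malformed line."""


class TICFUndefinedError(OncoIntegrateError):
    """A patient lacks one of the clinical components of the composite feature."""


class InsufficientCohortError(OncoIntegrateError):
    """An enriched cohort has too few rows with survival targets to train on."""


class ProviderError(OncoIntegrateError):
    """An external-knowledge provider failed after exhausting retries."""


class ConfigError(OncoIntegrateError):
    """Invalid pipeline or generator configuration."""
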