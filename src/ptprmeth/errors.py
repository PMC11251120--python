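"""Exception types shared across the package."""


class PtprMethError(Exception):
    """Base class for all package errors."""


class ValidationError(PtprMethError, ValueError):
    """Input data violates a structural or range contract."""


class ConfigurationError(PtprMethError, ValueError):
    """A configuration object is internally inconsistent."""


class IntegrationError(PtprMethError, ValueError):
    """Cross-platform integration cannot proceed (e.g. empty probe intersection)."""
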