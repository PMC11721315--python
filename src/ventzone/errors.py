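"""Exception types shared across the pipeline."""


class VentzoneError(Exception):
    """Base class for all package errors."""


class ConfigurationError(VentzoneError):
    """A config document, column mapping or zone table is unusable."""


class ValidationError(VentzoneError):
    """Input data violate a documented invariant (e.g. non-monotone time)."""
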