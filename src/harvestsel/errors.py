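class ConfigurationError(ValueError):
    """Invalid configuration (non-positive spacing, empty year list, ...)."""


class DataError(ValueError):
    """Input data violates a precondition (missing DOP, missing metadata, ...)."""
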