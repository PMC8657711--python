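"""Exception types shared across the pipeline."""


class LymphsigError(Exception):
    """Base class for package errors."""


class ConfigurationError(LymphsigError):
    """Invalid user-supplied configuration value."""


class DataIntegrityError(LymphsigError):
    """Input data contradicts itself (e.g. VCF ref base != genome base)."""
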