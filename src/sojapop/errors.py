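class SojapopError(Exception):
    """Base class for user-facing errors (CLI exit code 1)."""


class VcfParseError(SojapopError):
    """Raised when a VCF record cannot be parsed; carries the record number."""


class ConfigError(SojapopError):
    """Raised for invalid run configurations; message lists every violation."""
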