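class RaceqtlError(Exception):
    """Base class for pipeline errors."""


class ConfigError(RaceqtlError):
    """Invalid configuration or precondition violation."""


class FormatError(RaceqtlError):
    """Malformed input file."""
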