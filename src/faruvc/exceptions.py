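"""Package-wide exception types."""


class SpectrumFormatError(ValueError):
    """Malformed spectral input: bad row, non-ascending grid, too few points."""


class DomainError(ValueError):
    """Input violates a physical or contractual precondition."""


class ConfigError(KeyError):
    """A run configuration is missing or malformed; the message names the key."""
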