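"""Exception hierarchy for sencaf."""


class SencafError(Exception):
    """Base class for all sencaf errors (data or contract violations)."""


class DataError(SencafError):
    """Malformed or inconsistent input data."""


class ConfigError(SencafError):
    """Invalid pipeline or simulation configuration."""
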