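"""Exception types shared across the package."""


class ConfigurationError(ValueError):
    """Raised for invalid run configurations or maze geometry."""


class LogicError(RuntimeError):
    """Raised when an internal contract is violated (e.g. querying a wall cell)."""
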