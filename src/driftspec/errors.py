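"""Exception types shared across the package."""


class InvalidConfigError(ValueError):
    """A configuration value is outside its admissible range."""


class DomainError(ValueError):
    """An input violates an operation's mathematical preconditions."""
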