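"""Exception types shared across the package."""


class ConfigurationError(ValueError):
    """Invalid parameter combination (capacity, thresholds, scheme layout)."""


class InputError(ValueError):
    """Malformed or inconsistent input data."""
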