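"""Exception types shared across the package."""


class ConfigurationError(ValueError):
    """A parameter or configuration block violates a documented constraint."""


class InputError(ValueError):
    """An input table, track or count is inconsistent with its contract."""
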