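"""Exception types shared across the package."""


class ConfigurationError(ValueError):
    """An invalid parameter or configuration value, named in the message."""


class ShapeError(ValueError):
    """Operand dimensions are inconsistent; message names the operands."""


class InputError(ValueError):
    """Invalid runtime input (empty signal, bad segment, degenerate pair)."""
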