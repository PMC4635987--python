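"""Exception types shared across the package."""


class ConfigurationError(ValueError):
    """A model input references something that does not exist or is malformed."""


class ConfigValidationError(ConfigurationError):
    """Raised by config loading with the full list of violations, not just the first."""

    def __init__(self, violations: list[str]):
        self.violations = list(violations)
        super().__init__(
            "configuration invalid (%d violation%s):\n  - %s"
            % (len(violations), "" if len(violations) == 1 else "s", "\n  - ".join(violations))
        )


class NumericsError(ArithmeticError):
    """A computed quantity (probability, state value) became non-finite."""
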