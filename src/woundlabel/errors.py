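"""Exception types shared across the package."""


class WoundLabelError(Exception):
    """Base class for all package-specific errors."""


class DomainError(WoundLabelError, ValueError):
    """An argument violates an operation's precondition."""


class FormatError(WoundLabelError, ValueError):
    """A file exists but cannot be decoded as a supported image."""


class ConfigurationError(WoundLabelError, ValueError):
    """A palette or session configuration is invalid (e.g. empty palette)."""


class CompletenessError(WoundLabelError, ValueError):
    """A mask still contains unlabeled pixels where full labeling is required."""

    def __init__(self, unlabeled_count: int):
        self.unlabeled_count = int(unlabeled_count)
        super().__init__(f"mask contains {self.unlabeled_count} unlabeled pixel(s)")


class ScriptError(WoundLabelError, ValueError):
    """A session-script action failed; carries the zero-based action index."""

    def __init__(self, index: int, message: str):
        self.index = int(index)
        super().__init__(f"script action {self.index}: {message}")
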