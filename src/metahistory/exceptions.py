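"""Exception hierarchy shared across the package."""


class MetahistoryError(Exception):
    """Base class for all package-specific errors."""


class ConfigError(MetahistoryError, ValueError):
    """Invalid configuration; the message names the offending field."""

    def __init__(self, field: str, message: str):
        self.field = field
        super().__init__(f"{field}: {message}")


class TrialParseError(MetahistoryError, ValueError):
    """Malformed trial CSV; the message carries the offending row where known."""


class EmptyCellError(MetahistoryError, ValueError):
    """A conditioning cell contains no trials (or no trials of one stimulus class)."""


class ConstantColumnError(MetahistoryError, ValueError):
    """A binary column is constant, so an association coefficient is undefined."""


class SplitError(MetahistoryError, RuntimeError):
    """A usable train/test split could not be drawn within the retry budget."""


class ConvergenceError(MetahistoryError, RuntimeError):
    """An optimizer failed to converge; carries the best value found so far."""

    def __init__(self, message: str, best_value: float | None = None):
        self.best_value = best_value
        super().__init__(message)
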