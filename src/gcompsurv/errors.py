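"""Exception types shared across the package."""


class InputError(ValueError):
    """A data value violates a precondition (negative concentration, etc.)."""


class ConfigurationError(ValueError):
    """A configuration field is invalid; the message names the field."""


class NonConvergenceError(RuntimeError):
    """The hazard-model fit failed to converge (e.g. separation)."""

    def __init__(self, message: str, column: str | None = None):
        super().__init__(message)
        self.column = column


class PredictionError(ValueError):
    """Prediction requested for data the fitted model cannot score."""
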