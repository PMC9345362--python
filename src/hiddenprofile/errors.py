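"""Exception types shared across the package."""


class HiddenProfileError(Exception):
    """Base class for all package errors."""


class ConfigurationError(HiddenProfileError, ValueError):
    """Inconsistent or invalid game / model configuration."""


class DegenerateInputError(HiddenProfileError, ValueError):
    """Input with no variation where variation is required (e.g. z-scoring a constant)."""


class InsufficientDataError(HiddenProfileError, ValueError):
    """Not enough usable observations to carry out the requested computation."""


class TrainingFailureError(HiddenProfileError, RuntimeError):
    """Model training diverged or produced non-finite loss.

    Carries the loss trace up to the failure point in ``loss_trace``.
    """

    def __init__(self, message: str, loss_trace=None):
        super().__init__(message)
        self.loss_trace = list(loss_trace) if loss_trace is not None else []
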