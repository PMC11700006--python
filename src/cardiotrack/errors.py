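"""Exception hierarchy used across the pipeline."""


class CardiotrackError(Exception):
    """Base class for all package-specific errors."""


class InvalidParameterError(CardiotrackError, ValueError):
    """A physical or numerical parameter is outside its valid domain."""


class OutOfFieldError(CardiotrackError, ValueError):
    """A rendered object leaves the field of view.

    Carries ``frame``, the index of the first offending frame.
    """

    def __init__(self, message: str, frame: int | None = None):
        super().__init__(message)
        self.frame = frame


class DegenerateInputError(CardiotrackError, ValueError):
    """Input carries no usable signal (e.g. an all-zero frame)."""


class InsufficientDataError(CardiotrackError, ValueError):
    """Too few samples to compute the requested statistic."""


class ConfigurationError(CardiotrackError, ValueError):
    """An experiment or sequence configuration fails validation."""


class ContractError(CardiotrackError, ValueError):
    """Caller violated an interface contract (shape/length mismatch)."""
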