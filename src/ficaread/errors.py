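"""Exception hierarchy for the strip-reader pipeline."""


class FicaError(Exception):
    """Base class for all package errors."""


class DomainError(FicaError, ValueError):
    """An argument violates a documented precondition."""


class DegenerateSegmentationError(FicaError):
    """The gray histogram cannot support a two-class threshold.

    Raised for single-valued regions and for histograms where the
    entropy criterion is undefined at every candidate threshold.
    """

    def __init__(self, message: str, half: str | None = None):
        super().__init__(message if half is None else f"{half} half: {message}")
        self.half = half


class NoSignalError(FicaError):
    """Target-region gray does not exceed the sensor dark level, so the
    exposure controller has no proportionality to scale with."""


class StageError(FicaError):
    """Pipeline failure wrapped with the name of the stage that raised it."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage '{stage}': {cause}")
        self.stage = stage
        self.cause = cause
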