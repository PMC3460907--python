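"""Exception hierarchy for the pipeline."""


class FlyStripError(Exception):
    """Base class for all pipeline errors."""


class FormatError(FlyStripError, ValueError):
    """Input image has the wrong shape, dtype or channel count."""


class ParameterError(FlyStripError, ValueError):
    """A processing parameter is outside its valid range."""


class NoEmbryoError(FlyStripError):
    """No foreground blob survived segmentation.

    Parameters
    ----------
    stage : str
        Name of the pipeline stage at which the foreground vanished.
    """

    def __init__(self, stage: str, message: str | None = None):
        self.stage = stage
        super().__init__(message or f"no embryo foreground left after stage {stage!r}")
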