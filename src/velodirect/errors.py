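"""Exception hierarchy shared across the package."""


class VelodirectError(Exception):
    """Base class for all package-specific errors."""


class ParameterError(VelodirectError, ValueError):
    """Invalid kinetic or model parameter (e.g. non-positive rate)."""


class ConfigError(VelodirectError, ValueError):
    """Invalid simulator / pipeline configuration."""


class EmptyResultError(VelodirectError, ValueError):
    """An operation filtered away every gene or feature."""


class ProvenanceError(VelodirectError, ValueError):
    """A layer transformation was applied in the wrong order (e.g. double normalize)."""


class ShapeError(VelodirectError, ValueError):
    """Mismatched matrix / metadata shapes or gene sets."""


class StratificationError(VelodirectError, ValueError):
    """A class is too small for the requested stratified split or CV."""


class ModelIOError(VelodirectError, ValueError):
    """Serialized model file is corrupt or has an unsupported version."""


class PipelineStageError(VelodirectError, RuntimeError):
    """A named pipeline stage failed; the original exception is chained."""

    def __init__(self, stage: str, message: str = ""):
        self.stage = stage
        super().__init__(f"pipeline stage '{stage}' failed" + (f": {message}" if message else ""))
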