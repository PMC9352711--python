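"""Exception hierarchy shared by all pipeline stages."""


class TLCQuantError(Exception):
    """Base class for all errors raised by this package."""


class ImagingError(TLCQuantError):
    """Invalid image data or an illegal image operation."""


class PlateNotFoundError(TLCQuantError):
    """Automatic plate detection failed; manual corner entry is required."""


class GeometryError(TLCQuantError):
    """Degenerate or invalid plate quadrilateral."""


class DensitometryError(TLCQuantError):
    """Background fitting or spot extraction failed."""


class CalibrationError(TLCQuantError):
    """Reference annotations cannot support a calibration line."""


class BundleSchemaError(TLCQuantError):
    """A result bundle is missing a mandatory file or field."""


class ValidationStatsError(TLCQuantError):
    """Invalid input to a performance-evaluation statistic."""


class PipelineError(TLCQuantError):
    """A pipeline stage failed; the message names the stage."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")
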