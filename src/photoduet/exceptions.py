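"""Exception hierarchy for photoduet."""


class PhotoduetError(Exception):
    """Base class for all photoduet errors."""


class ConfigError(PhotoduetError):
    """Invalid simulation or analysis configuration."""


class FormatError(PhotoduetError):
    """On-disk session data violates the format contract."""


class DegenerateFitError(PhotoduetError):
    """Isosbestic regression cannot be computed (e.g. constant 405 trace)."""


class StageError(PhotoduetError):
    """A pipeline stage failed; carries the stage name and offending input."""

    def __init__(self, stage: str, detail: str):
        self.stage = stage
        self.detail = detail
        super().__init__(f"stage '{stage}' failed: {detail}")
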