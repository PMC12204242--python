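"""Exception hierarchy shared across the pipeline.

Every stage raises a subclass of :class:`PectusError` so the CLI can map
failures onto its exit codes (2 config, 3 data, 4 pipeline stage).
"""


class PectusError(Exception):
    """Base class for all package errors."""


class ParameterError(PectusError, ValueError):
    """An input parameter violates a documented bound."""


class ResolutionError(ParameterError):
    """The requested raster grid cannot contain the geometry."""


class GeometryError(PectusError):
    """A contour or mask violates a geometric contract."""


class LandmarkError(GeometryError):
    """A landmark required by the index formulas could not be located."""


class DataError(PectusError):
    """Input files are missing, inconsistent, or unreadable."""


class StageError(PectusError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage
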