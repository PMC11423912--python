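"""Exception hierarchy shared across the pipeline stages."""


class CochleaQuantError(Exception):
    """Base class for all package errors."""


class ConfigurationError(CochleaQuantError, ValueError):
    """A preset or run configuration field is invalid; the message names the field."""


class AnalysisError(CochleaQuantError, RuntimeError):
    """An image could not be analysed (e.g. no tissue detected)."""


class NoBoundaryError(AnalysisError):
    """A marker profile has no qualifying threshold crossing for a boundary."""

    def __init__(self, boundary: str, detail: str = ""):
        self.boundary = boundary
        msg = f"NoBoundary({boundary})"
        if detail:
            msg += f": {detail}"
        super().__init__(msg)


class InconsistentBoundariesError(AnalysisError):
    """Threshold crossings violate the medial->lateral domain ordering."""
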