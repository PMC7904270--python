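"""Exception hierarchy for gazekit."""


class GazeKitError(Exception):
    """Base class for all gazekit errors."""


class ValidationError(GazeKitError, ValueError):
    """Invalid specification, parameter or input value."""


class ExtractionError(GazeKitError):
    """Eye-ROI extraction failed (degenerate box, missing landmarks)."""


class BoundaryError(GazeKitError):
    """A snakuscule probe extends outside the image."""


class EstimationError(GazeKitError):
    """Head-pose estimation diverged or the configuration is degenerate."""


class FitError(GazeKitError):
    """Mapping-function fit is underdetermined or rank deficient."""


class EvaluationError(GazeKitError):
    """Session evaluation cannot proceed (e.g. too few calibration frames)."""
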