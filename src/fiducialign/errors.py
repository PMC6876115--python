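"""Exception hierarchy for the fiducialign package."""


class FiducialignError(Exception):
    """Base class for all package errors."""


class InvalidParameterError(FiducialignError, ValueError):
    """A parameter violates a documented precondition."""


class STLParseError(FiducialignError, ValueError):
    """Malformed STL input; the message names the offending byte offset or line."""


class DegenerateConfigurationError(FiducialignError, ValueError):
    """Landmark configuration too degenerate for pose estimation."""


class RegistrationFailureError(FiducialignError, RuntimeError):
    """Registration could not proceed (e.g. no correspondences after rejection)."""


class EmptyScanError(FiducialignError, RuntimeError):
    """Virtual scan produced no surface (all faces culled)."""


class EmptySelectionError(FiducialignError, ValueError):
    """A crop/segmentation region selected no faces."""


class EmptyReportError(FiducialignError, RuntimeError):
    """All deviation samples were excluded by the cutoff."""


class UndefinedTestError(FiducialignError, ValueError):
    """A statistical test is undefined for the given data (e.g. all-zero differences)."""


class WorkflowStepError(FiducialignError, RuntimeError):
    """A pipeline step failed; carries the 1-based step index."""

    def __init__(self, step: int, message: str):
        self.step = step
        super().__init__(f"workflow step {step} failed: {message}")
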