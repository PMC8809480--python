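"""Exception hierarchy for the iCAT pipeline."""


class ICATError(Exception):
    """Base class for all pipeline errors."""


class SingularTransformError(ICATError):
    """An affine transform with (near-)zero determinant cannot be inverted."""


class StoreFormatError(ICATError):
    """A tile-store record or image is missing or malformed."""


class RenderError(ICATError):
    """Composite rendering was requested over a region no tile covers."""


class SectionDetectionError(ICATError):
    """Section segmentation could not place the requested number of markers."""


class SpotDetectionError(ICATError):
    """No cathodoluminescent spots could be localized in the camera frame."""


class RegistrationError(ICATError):
    """A registration stage failed (degenerate correspondences, rank deficiency,
    or an implausible recovered transform)."""


class ConnectivityError(ICATError):
    """The point-match graph is disconnected; alignment cannot be solved as one
    system. Carries the weakly connected components for diagnostics."""

    def __init__(self, message: str, components=None):
        super().__init__(message)
        self.components = components or []


class SolverError(ICATError):
    """The sparse least-squares system is rank deficient or ill posed."""


class PipelineError(ICATError):
    """A pipeline stage aborted; partial state is left in the store."""
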