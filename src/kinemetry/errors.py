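"""Exception hierarchy for the kinemetry pipeline.

Stage-level failures (a frame out of plane, a missing joint, a depth hole)
are recoverable and become gaps in the angle series; recording-level
failures (lost synchronization, too-long gaps) mark the whole recording as
lost in the availability grid, mirroring how the validation study
discarded recordings rather than aborting the analysis.
"""


class KinemetryError(Exception):
    """Base class for all pipeline errors."""


class InvalidDepthError(KinemetryError):
    """Depth value is non-positive or non-finite."""


class AsynchronousFrameError(KinemetryError):
    """No depth frame within tolerance of the landmark frame timestamp."""


class BehindCameraError(KinemetryError):
    """A joint has non-positive depth after the camera-orientation rotation."""


class MissingJointError(KinemetryError):
    """A joint required by a basis or angle request is absent from the frame."""


class DegenerateBasisError(KinemetryError):
    """Body-basis landmarks are collinear or coincident."""


class DegenerateVectorError(KinemetryError):
    """The moving joint vector has (near) zero length."""


class OutOfPlaneError(KinemetryError):
    """The moving vector exceeds the out-of-plane tolerance for the plane."""

    def __init__(self, deviation_deg: float, tolerance_deg: float):
        self.deviation_deg = deviation_deg
        self.tolerance_deg = tolerance_deg
        super().__init__(
            f"moving vector is {deviation_deg:.2f} deg out of plane "
            f"(tolerance {tolerance_deg:.2f} deg)"
        )


class EmptySeriesError(KinemetryError):
    """Every frame of a stream failed to yield an angle."""


class NoPeakError(KinemetryError):
    """Peak detection found no repetition maximum."""


class SynchronizationError(KinemetryError):
    """Peak counts disagree across streams; the recording cannot be aligned."""


class RecordingLostError(KinemetryError):
    """Recording-level failure; the recording is dropped from the analysis."""


class MovementCodeError(KinemetryError):
    """A movement code contains an unknown token."""


class UndefinedCorrelationError(KinemetryError):
    """Pearson correlation is undefined (zero-variance series)."""
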