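"""Exception hierarchy shared across the pipeline stages."""


class EngageKitError(Exception):
    """Base class for all pipeline errors."""


class ParseError(EngageKitError):
    """A keypoint or annotation record could not be parsed."""


class SchemaError(EngageKitError):
    """A record violates the keypoint schema (wrong counts/shapes)."""


class EmptyTrackError(EngageKitError):
    """No usable person detections in any frame."""


class MissingKeypointError(EngageKitError):
    """A keypoint required by a feature is absent."""

    def __init__(self, joint: str, message: str | None = None):
        self.joint = joint
        super().__init__(message or f"required keypoint absent: {joint}")


class TooShortError(EngageKitError):
    """A track or segment is too short for the requested operation."""


class IntervalError(EngageKitError):
    """A behavior event has stop <= start."""


class VocabularyError(EngageKitError):
    """A behavior name is outside the closed six-behavior vocabulary."""


class AlignmentError(EngageKitError):
    """Feature and label streams share no frames."""


class MissingFaceError(EngageKitError):
    """Face keypoints entirely absent for a segment."""


class EmptyDatasetError(EngageKitError):
    """Windowing produced no sequences."""


class ParameterError(EngageKitError):
    """An operation parameter is outside its valid range."""


class ShapeError(EngageKitError):
    """Model input shape inconsistent with the data."""


class ConfigError(EngageKitError):
    """Invalid run or synthesis configuration."""
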