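"""Exception hierarchy for the risk-assessment pipeline.

Every error raised by the library derives from :class:`FuzzyRulaError` so
callers (and the CLI) can catch pipeline failures with a single handler.
"""


class FuzzyRulaError(Exception):
    """Base class for all library errors."""


class PoseValidationError(FuzzyRulaError):
    """A pose file or in-memory sequence violates the skeleton data model."""


class MissingJointError(FuzzyRulaError):
    """A frame lacks a joint required by the requested computation."""

    def __init__(self, joint: str, frame_index: int | None = None):
        self.joint = joint
        self.frame_index = frame_index
        where = f" in frame {frame_index}" if frame_index is not None else ""
        super().__init__(f"required joint '{joint}' is missing{where}")


class DegenerateGeometryError(FuzzyRulaError):
    """A direction vector is too short to define an angle."""


class ConfigError(FuzzyRulaError):
    """A fuzzy-system, task-profile or run configuration is invalid."""


class NoActivationError(FuzzyRulaError):
    """No fuzzy rule fired for a frame (empty aggregated membership)."""


class FrameInvalidError(FuzzyRulaError):
    """A frame is missing an angle required by the fuzzy system."""


class ConstructionError(FuzzyRulaError):
    """A synthetic pose could not be constructed for a requested angle set."""
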