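"""Exception hierarchy. Everything user-facing derives from JawstrainError."""


class JawstrainError(Exception):
    """Base class for all package errors."""


class ValidationError(JawstrainError, ValueError):
    """Invalid parameter or malformed input object."""


class SizingError(JawstrainError):
    """Requested geometry does not fit the voxel domain."""


class PlacementError(JawstrainError):
    """Could not place a synthetic feature after bounded retries."""


class ConvergenceError(JawstrainError):
    """Iterative construction failed to reach its target."""


class FitError(JawstrainError):
    """Degenerate data for a model fit."""


class CalibrationError(JawstrainError):
    """Relative calibration failed on the reference curves."""


class MapRejectedError(JawstrainError):
    """Too many failed pixels in a nanomechanical map."""


class MeasurementError(JawstrainError):
    """A morphometric measurement could not be taken (e.g. missing label)."""


class MeshError(JawstrainError):
    """Voxel volume cannot be meshed."""


class RigidBodyError(JawstrainError):
    """Constrained FE system still has rigid-body freedom."""


class ConfigurationError(JawstrainError):
    """Missing or inconsistent run configuration."""


class PartialResultError(JawstrainError):
    """A multi-cell experiment failed part-way; completed cells are preserved.

    The completed cells are available on the ``completed`` attribute.
    """

    def __init__(self, message: str, completed: dict | None = None):
        super().__init__(message)
        self.completed = completed or {}
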