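"""Exception hierarchy shared across the pipeline."""


class PerfectsynError(Exception):
    """Base class for package errors."""


class ValidationError(PerfectsynError, ValueError):
    """An input violates a precondition (non-finite values, empty mask, ...)."""


class GridMismatchError(ValidationError):
    """Two objects that must share a voxel grid do not."""


class PlacementError(PerfectsynError):
    """Virtual couch cannot be placed without overlapping the body."""


class ConvergenceError(PerfectsynError):
    """A registration optimizer failed to improve its objective."""


class CoverageError(PerfectsynError):
    """Patch stitching was asked to reconstruct voxels no patch covers."""


class ConfigError(PerfectsynError, ValueError):
    """An invalid configuration value (negative weight, bad variant, ...)."""
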