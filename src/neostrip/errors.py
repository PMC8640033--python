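"""Exception hierarchy for neostrip.

All package errors derive from :class:`NeostripError` so callers can catch one
base class at the pipeline boundary.
"""


class NeostripError(Exception):
    """Base class for all neostrip errors."""


class VolumeIOError(NeostripError):
    """File missing or not a readable NIfTI volume."""


class DimensionalityError(VolumeIOError):
    """Image is not a 3D volume (e.g. a 4D functional series)."""


class ValidationError(NeostripError):
    """Input data violates an invariant (non-finite voxels, bad spacing...)."""


class ParameterError(NeostripError):
    """A parameter is outside its documented domain."""


class GridMismatchError(NeostripError):
    """Two grids (mask/volume/mask) that must be aligned are not."""


class DegenerateHistogramError(NeostripError):
    """Histogram has zero spread (all values identical) — no valley exists."""


class DataError(NeostripError):
    """Dataset unusable for the requested fit (e.g. fewer points than clusters)."""


class EmptyClusterError(NeostripError):
    """A cluster received no elements under hard assignment."""

    def __init__(self, index: int):
        self.index = index
        super().__init__(f"cluster {index} is empty after hard assignment")


class UndefinedScoreError(NeostripError):
    """Requested score is undefined for the given masks (e.g. both empty)."""
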