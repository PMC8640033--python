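"""NIfTI volume I/O, RAS reorientation and resampling to the standard grid.

The pipeline operates in the RAS voxel convention: axis 0 runs left→right,
axis 1 posterior→anterior, axis 2 inferior→superior, and an *axial slice* is a
fixed-third-index plane.  Voxel indices are 0-based throughout.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
from scipy import ndimage

from .errors import DimensionalityError, ParameterError, ValidationError, VolumeIOError

log = logging.getLogger(__name__)

STANDARD_SPACING = (1.0, 1.0, 1.0)
STANDARD_SHAPE = (256, 256, 198)


@dataclass
class Volume:
    """A 3D scalar intensity grid with physical-space metadata.

    ``affine`` is the voxel→world (mm) map in NIfTI convention and is the
    source of truth; ``spacing``, ``orientation`` and ``origin`` are derived
    views of it.
    """

    data: np.ndarray
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=np.float64)
        self.affine = np.asarray(self.affine, dtype=np.float64)
        if self.data.ndim != 3:
            raise DimensionalityError(
                f"Volume requires 3D data, got {self.data.ndim}D"
            )
        if not np.all(np.asarray(self.spacing) > 0):
            raise ValidationError(f"non-positive spacing {self.spacing}")

    @property
    def spacing(self) -> tuple[float, float, float]:
        return tuple(np.sqrt((self.affine[:3, :3] ** 2).sum(axis=0)))

    @property
    def orientation(self) -> str:
        return "".join(nib.orientations.aff2axcodes(self.affine))

    @property
    def origin(self) -> tuple[float, float, float]:
        return tuple(self.affine[:3, 3])

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def copy_with(self, data: np.ndarray) -> "Volume":
        return Volume(data=np.asarray(data, dtype=np.float64), affine=self.affine.copy())


@dataclass
class BinaryMask:
    """Boolean grid (2D slice or 3D volume) aligned to a parent Volume grid."""

    data: np.ndarray
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=bool)
        self.affine = np.asarray(self.affine, dtype=np.float64)
        if self.data.ndim not in (2, 3):
            raise DimensionalityError("BinaryMask must be 2D or 3D")

    @property
    def shape(self):
        return self.data.shape

    def count(self) -> int:
        return int(self.data.sum())


def _check_finite(data: np.ndarray) -> np.ndarray:
    bad = ~np.isfinite(data)
    if bad.any():
        raise ValidationError(f"{int(bad.sum())} non-finite voxels in input volume")
    return data


def read_volume(path) -> Volume:
    """Load a 3D NIfTI-1/NIfTI-2 volume.

    Negative intensities (possible after scanner scaling) are clipped to 0
    with a logged count; all histogram-based stages assume non-negative data.
    """
    path = Path(path)
    if not path.exists():
        raise VolumeIOError(f"no such file: {path}")
    try:
        img = nib.load(str(path))
    except Exception as exc:  # nibabel raises several types
        raise VolumeIOError(f"cannot read {path}: {exc}") from exc
    data = np.asanyarray(img.dataobj)
    # trailing singleton dimensions (3D stored as 4D with size-1 time axis) are legal
    while data.ndim > 3 and data.shape[-1] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise DimensionalityError(f"{path}: expected 3D image, got {data.ndim}D")
    data = _check_finite(np.asarray(data, dtype=np.float64))
    n_neg = int((data < 0).sum())
    if n_neg:
        log.info("clipping %d negative voxels to 0 in %s", n_neg, path)
        data = np.clip(data, 0, None)
    return Volume(data=data, affine=img.affine)


def write_volume(v: Volume, path) -> None:
    nib.save(nib.Nifti1Image(v.data, v.affine), str(path))


def write_mask(m: BinaryMask, path) -> None:
    """Masks are written as uint8 NIfTI with values {0, 1}."""
    nib.save(nib.Nifti1Image(m.data.astype(np.uint8), m.affine), str(path))


def read_mask(path) -> BinaryMask:
    v = read_volume(path)
    return BinaryMask(data=v.data > 0.5, affine=v.affine)


def _obliquity(affine: np.ndarray) -> float:
    """Largest off-dominant direction-cosine magnitude (0 for axis-aligned)."""
    R = affine[:3, :3]
    cols = R / np.linalg.norm(R, axis=0)
    worst = 0.0
    for j in range(3):
        c = np.abs(cols[:, j])
        c = np.delete(c, np.argmax(c))
        worst = max(worst, float(c.max()))
    return worst


def reorient_to_ras(v: Volume) -> Volume:
    """Permute/flip axes so the volume is in RAS orientation.

    Only axis permutations and flips are applied, so the multiset of voxel
    values is preserved exactly.  Oblique affines (off-axis rotation) are
    reoriented to the nearest canonical axes with a warning.
    """
    if _obliquity(v.affine) > 1e-3:
        log.warning("oblique affine (obliquity %.4f); applying nearest-canonical reorientation",
                    _obliquity(v.affine))
    if v.orientation == "RAS":
        return Volume(data=v.data.copy(), affine=v.affine.copy())
    ornt = nib.orientations.io_orientation(v.affine)
    data = nib.orientations.apply_orientation(v.data, ornt)
    affine = v.affine @ nib.orientations.inv_ornt_aff(ornt, v.data.shape)
    return Volume(data=data, affine=affine)


def _target_affine(v: Volume, spacing, shape) -> np.ndarray:
    """RAS-aligned affine for a grid of `shape` at `spacing`, centered on v's FOV."""
    spacing = np.asarray(spacing, float)
    shape = np.asarray(shape, int)
    # physical center of the input field of view
    center_vox = (np.asarray(v.shape) - 1) / 2.0
    center_mm = nib.affines.apply_affine(v.affine, center_vox)
    aff = np.eye(4)
    aff[:3, :3] = np.diag(spacing)
    aff[:3, 3] = center_mm - spacing * (shape - 1) / 2.0
    return aff


def resample_standard(
    v: Volume,
    spacing=STANDARD_SPACING,
    shape=STANDARD_SHAPE,
    interp: str = "linear",
) -> Volume:
    """Resample an RAS volume onto the standard isotropic grid.

    The output grid is centered on the input field of view.  ``interp`` is
    "linear" for intensity volumes and "nearest" for masks.
    """
    if v.orientation != "RAS":
        raise ValidationError("resample_standard requires an RAS volume")
    if interp not in ("linear", "nearest"):
        raise ParameterError(f"unknown interpolation {interp!r}")
    tgt_aff = _target_affine(v, spacing, shape)
    # map target voxel -> world -> input voxel
    M = np.linalg.inv(v.affine) @ tgt_aff
    order = 1 if interp == "linear" else 0
    out = ndimage.affine_transform(
        v.data, M[:3, :3], offset=M[:3, 3], output_shape=tuple(shape),
        order=order, mode="constant", cval=0.0,
    )
    # warn when the input FOV does not fit inside the requested grid
    in_corners = np.array(np.meshgrid(*[[0, s - 1] for s in v.shape])).reshape(3, -1).T
    mm = nib.affines.apply_affine(v.affine, in_corners)
    vox = nib.affines.apply_affine(np.linalg.inv(tgt_aff), mm)
    lo, hi = vox.min(axis=0), vox.max(axis=0)
    span = np.maximum(hi - lo, 1e-9)
    clipped = np.clip(lo * -1, 0, None) + np.clip(hi - (np.asarray(shape) - 1), 0, None)
    frac = float(np.max(clipped / span))
    if frac > 0:
        log.warning("input FOV exceeds target grid; up to %.1f%% clipped per axis", 100 * frac)
    return Volume(data=out, affine=tgt_aff)


def resample_mask_to(mask: BinaryMask, target: Volume) -> BinaryMask:
    """Nearest-neighbor resampling of a 3D mask onto another volume's grid.

    Used to carry the final brain mask back to the native input grid.
    """
    M = np.linalg.inv(mask.affine) @ target.affine
    out = ndimage.affine_transform(
        mask.data.astype(np.float32), M[:3, :3], offset=M[:3, 3],
        output_shape=target.shape, order=0, mode="constant", cval=0.0,
    )
    return BinaryMask(data=out > 0.5, affine=target.affine.copy())
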