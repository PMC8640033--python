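"""Synthetic infant-head phantom with ground-truth brain and eye masks.

The phantom emulates the appearance of an infant head in a T2-weighted image
on the pipeline's RAS grid: nested ellipsoidal shells of scalp/fat (bright),
skull (dark), dura/muscle (dark), a bright CSF rim, mid-intensity brain
tissue, and two bright ~20 mm eyeballs protruding anterior–inferior of the
cranium.  A thin dark dura/muscle layer is modeled explicitly because
separating exactly that tissue from brain is what the fuzzy-clustering stage
exists for.  Partial-volume blur, a smooth multiplicative bias field and
additive Gaussian noise give the image MR-like statistics.

Ground truth: ``truth_brain`` is everything inside the inner dura table
(brain tissue plus the interior CSF rim); ``truth_eyes`` is the two spheres.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .errors import ParameterError
from .volume_io import BinaryMask, Volume


@dataclass
class PhantomSpec:
    """Geometry, tissue intensities and corruption levels of the phantom.

    The default 128×128×100 grid at 1 mm holds a scaled-down (~80×96×80 mm)
    head so the full pipeline runs in seconds; ``fullsize()`` gives a
    realistic head on the 256×256×198 standard grid.  Intensities follow the
    infant T2w ordering air < skull < dura < brain tissue < scalp < CSF ≈ eyes.
    """

    shape: tuple[int, int, int] = (128, 128, 100)
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    center_mm: tuple[float, float, float] = (64.0, 58.0, 50.0)
    # ellipsoid semi-axes (mm): a thin bright scalp/fat layer over dark skull
    # and dura shells, then a thin bright CSF rim around the brain.  The head
    # nearly fills the field of view and is taller than the axial coverage
    # (a mid-cranial acquisition block), so every axial slice cuts brain
    # tissue — as in a brain-focused clinical acquisition.
    scalp_semi: tuple[float, float, float] = (46.0, 56.0, 62.0)
    skull_semi: tuple[float, float, float] = (44.0, 54.0, 60.0)
    dura_semi: tuple[float, float, float] = (40.0, 50.0, 56.0)
    csf_semi: tuple[float, float, float] = (37.5, 47.5, 53.5)
    brain_semi: tuple[float, float, float] = (36.0, 46.0, 52.0)
    eye_diameter_mm: float = 20.0
    # anterior–inferior of the brain center; the spheres poke slightly out of
    # the anterior FOV edge, as eyes often do in brain-focused scans
    eye_centers_mm: tuple = ((47.0, 119.0, 28.0), (81.0, 119.0, 28.0))
    # tissue mean intensities (arbitrary units)
    air: float = 5.0
    skull: float = 12.0
    dura: float = 20.0
    brain: float = 110.0
    scalp: float = 160.0
    csf: float = 200.0
    eyes: float = 210.0
    # corruption
    pv_blur_mm: float = 0.45       # partial-volume blur; FWHM ~1.06 mm = the
                                   # point-spread of a 1 mm isotropic acquisition
    noise_sd: float = 4.0
    bias_amplitude: float = 0.10   # multiplicative field spans 1 ± amplitude
    seed: int = 0
    # optional pathology: (center_mm, radius_mm, intensity) blobs inside brain
    lesions: tuple = ()
    include_eyes: bool = True

    @classmethod
    def fullsize(cls, **overrides) -> "PhantomSpec":
        """Realistic head on the full 256×256×198 standard grid."""
        # exactly 2x the default geometry, so the head fills the 256-voxel
        # FOV in the same proportions; the 20 mm eyes are anatomical size and
        # sit just outside the anterior skull
        s = 2.0
        base = dict(
            shape=(256, 256, 198),
            center_mm=(128.0, 116.0, 99.0),
            scalp_semi=(46 * s, 56 * s, 62 * s),
            skull_semi=(44 * s, 54 * s, 60 * s),
            dura_semi=(40 * s, 50 * s, 56 * s),
            csf_semi=(37.5 * s, 47.5 * s, 53.5 * s),
            brain_semi=(36 * s, 46 * s, 52 * s),
            eye_centers_mm=((128 - 34.0, 228.0, 55.0),
                            (128 + 34.0, 228.0, 55.0)),
        )
        base.update(overrides)
        return cls(**base)

    @classmethod
    def with_lesion(cls, kind: str = "hyper", **overrides) -> "PhantomSpec":
        """Pathology presets: interior hyper-/hypo-intense blob or enlarged CSF."""
        spec = cls(**overrides)
        if kind == "hyper":
            spec.lesions = (((56.0, 64.0, 52.0), 8.0, 190.0),)
        elif kind == "hypo":
            spec.lesions = (((56.0, 64.0, 52.0), 8.0, 45.0),)
        elif kind == "big_csf":
            spec.brain_semi = tuple(a - 2.5 for a in spec.brain_semi)
        else:
            raise ParameterError(f"unknown lesion preset {kind!r}")
        return spec


def _ellipsoid(coords, center, semi) -> np.ndarray:
    x, y, z = coords
    cx, cy, cz = center
    ax, ay, az = semi
    return ((x - cx) / ax) ** 2 + ((y - cy) / ay) ** 2 + ((z - cz) / az) ** 2 <= 1.0


def _sphere(coords, center, radius) -> np.ndarray:
    x, y, z = coords
    cx, cy, cz = center
    return (x - cx) ** 2 + (y - cy) ** 2 + (z - cz) ** 2 <= radius ** 2


def _smooth_bias_field(shape, amplitude, rng) -> np.ndarray:
    """Smooth multiplicative field 1 ± amplitude from an upsampled coarse grid."""
    coarse = rng.normal(size=(4, 4, 3))
    zoom = [s / c for s, c in zip(shape, coarse.shape)]
    f = ndimage.zoom(coarse, zoom, order=3)[: shape[0], : shape[1], : shape[2]]
    f = ndimage.gaussian_filter(f, sigma=min(shape) / 8)
    f -= f.mean()
    m = np.abs(f).max()
    if m > 0:
        f /= m
    return 1.0 + amplitude * f


def generate_phantom(spec: PhantomSpec | None = None):
    """Build (volume, truth_brain, truth_eyes) deterministically from a seed.

    The intensity image is Σ region means × indicators, blurred for partial
    volume, multiplied by a smooth bias field, plus Gaussian noise, clipped
    at 0.  Raises if the eyes overlap the ground-truth brain beyond a 0.5%
    tolerance of the eye volume.
    """
    spec = spec or PhantomSpec()
    spacing = np.asarray(spec.spacing, float)
    grids = np.meshgrid(
        *[np.arange(n) * d for n, d in zip(spec.shape, spacing)], indexing="ij"
    )

    ideal = np.full(spec.shape, spec.air, dtype=np.float64)
    for semi, intensity in [
        (spec.scalp_semi, spec.scalp),
        (spec.skull_semi, spec.skull),
        (spec.dura_semi, spec.dura),
        (spec.csf_semi, spec.csf),
        (spec.brain_semi, spec.brain),
    ]:
        ideal[_ellipsoid(grids, spec.center_mm, semi)] = intensity

    brain_region = _ellipsoid(grids, spec.center_mm, spec.brain_semi)
    truth_brain = _ellipsoid(grids, spec.center_mm, spec.csf_semi)

    for center, radius, intensity in spec.lesions:
        blob = _sphere(grids, center, radius)
        if not (blob & brain_region).sum() == blob.sum():
            raise ParameterError("lesion must lie inside the brain region")
        ideal[blob] = intensity

    truth_eyes = np.zeros(spec.shape, dtype=bool)
    if spec.include_eyes:
        r = spec.eye_diameter_mm / 2.0
        for c in spec.eye_centers_mm:
            eye = _sphere(grids, c, r)
            truth_eyes |= eye
            ideal[eye] = spec.eyes
        overlap = int((truth_eyes & truth_brain).sum())
        if overlap > 0.005 * truth_eyes.sum():
            raise ParameterError(
                f"eyes overlap the brain region by {overlap} voxels"
            )

    rng = np.random.default_rng(spec.seed)
    img = ideal
    if spec.pv_blur_mm > 0:
        img = ndimage.gaussian_filter(img, sigma=spec.pv_blur_mm / spacing)
    if spec.bias_amplitude > 0:
        img = img * _smooth_bias_field(spec.shape, spec.bias_amplitude, rng)
    if spec.noise_sd > 0:
        img = img + rng.normal(0.0, spec.noise_sd, size=spec.shape)
    img = np.clip(img, 0.0, None)

    affine = np.diag([*spacing, 1.0])
    vol = Volume(data=img, affine=affine)
    return (
        vol,
        BinaryMask(data=truth_brain, affine=affine.copy()),
        BinaryMask(data=truth_eyes, affine=affine.copy()),
    )
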