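"""Geometric eye detection and removal.

Eyes in T2w infant images are bright, roughly circular (≈ 20 mm diameter) and
sit in the anterior half of inferior axial slices.  The stage (1) locates the
first axial slice that can contain eyes from a sagittal/coronal geometric
construction, (2) thresholds bright candidate regions per slice, and
(3) keeps candidates whose shape matches a 20 mm disk under the bidirectional
Hausdorff distance, subtracting them from the brain mask.

Axes follow the package's RAS convention: axis 0 left→right, axis 1
posterior→anterior, axis 2 inferior→superior.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import directed_hausdorff
from skimage import measure, morphology

from .errors import ValidationError
from .volume_io import BinaryMask, Volume

log = logging.getLogger(__name__)


@dataclass
class EyeCandidate:
    """A labeled bright connected region in an axial slice."""

    label: int
    indices: np.ndarray            # (N, 2) voxel indices (x, y) in the slice
    pixels_mm: np.ndarray          # (N, 2) the same points in mm
    centroid_mm: np.ndarray        # (2,)
    anterior_fraction: float
    area_mm2: float
    hausdorff_mm: float | None = None


def eye_intensity_threshold(
    v: Volume, mask: np.ndarray | None = None, percentile: float = 60.0
) -> float:
    """Brightness threshold at the given percentile of head intensities.

    The 60th percentile sits just above the white/gray matter bulk (which
    makes up roughly 60% of the head histogram in young infants), so the
    super-threshold voxels are CSF, fat and the eyeballs.  ``mask`` restricts
    the distribution to the head (the stacked background masks); without it,
    all positive voxels are used.
    """
    vals = v.data[mask] if mask is not None else v.data
    vals = vals[vals > 0]
    if vals.size == 0:
        raise ValidationError("no positive voxels for eye threshold")
    return float(np.percentile(vals, percentile))


def locate_eye_start(
    v: Volume,
    bg3d: BinaryMask,
    offset_mm: float = 15.0,
    min_divergence_frac: float = 0.015,
) -> int | None:
    """Detect the starting (most superior) axial index of the eye region.

    1. pick the sagittal slice of ``bg3d`` with the longest anterior–posterior
       extent; 2. step ``offset_mm`` posterior from its front-most occupied
       line (skull thickness + eye radius); 3. take the coronal slice through
       that line and project its intensities along left–right; 4. match a
       Gaussian (same mean/SD/area construction as the histogram partition) to
       the projection; the superior–inferior position of maximum
       projection − Gaussian divergence marks the eyes.  Eye removal then
       applies from the returned index toward the inferior end.

    The coronal slice is masked with the background mask before projecting so
    the air baseline does not dilute the eye peak.  Returns None (eye removal
    disabled) when the projection is degenerate or the peak divergence is
    below ``min_divergence_frac`` of the projection area — e.g. an eyeless,
    featureless head.
    """
    if bg3d.data.ndim != 3 or bg3d.data.shape != v.shape:
        raise ValidationError("bg3d must be a 3D mask on the volume grid")
    occ = bg3d.data
    if not occ.any():
        return None
    # 1. sagittal slice (fixed x) with longest A-P extent
    extents = np.zeros(occ.shape[0], dtype=int)
    for x in range(occ.shape[0]):
        ys = np.nonzero(occ[x].any(axis=1))[0]
        if ys.size:
            extents[x] = ys[-1] - ys[0] + 1
    x_star = int(np.argmax(extents))
    ys = np.nonzero(occ[x_star].any(axis=1))[0]
    y_front = int(ys[-1])
    # 2. step posterior by offset_mm
    y_line = y_front - int(round(offset_mm / v.spacing[1]))
    y_line = max(0, min(y_line, v.shape[1] - 1))
    # 3. left-right projection of the (background-removed) coronal slice:
    # one value per axial row
    coronal = v.data[:, y_line, :] * occ[:, y_line, :]
    proj = coronal.sum(axis=0)
    area = float(proj.sum())
    if area <= 0:
        log.warning("empty coronal projection; eye removal disabled")
        return None
    z = np.arange(proj.size, dtype=np.float64)
    mu = float((z * proj).sum() / area)
    sd = float(np.sqrt(np.maximum((proj * (z - mu) ** 2).sum() / area, 0.0)))
    if sd == 0:
        log.warning("degenerate projection (zero spread); eye removal disabled")
        return None
    g = np.exp(-0.5 * ((z - mu) / sd) ** 2)
    gauss = area * g / g.sum()
    divergence = proj - gauss
    peak = float(divergence.max())
    if peak < min_divergence_frac * area:
        log.info("projection divergence %.3f below %.3f of area; eye removal disabled",
                 peak, min_divergence_frac)
        return None
    return int(np.argmax(divergence))


def eye_candidates(
    slice_2d: np.ndarray,
    T: float,
    spacing=(1.0, 1.0),
    min_area_mm2: float = 25.0,
    max_area_mm2: float = 1000.0,
) -> list[EyeCandidate]:
    """Bright 8-connected regions in the anterior half of an axial slice.

    Components with anterior_fraction < 0.5 are dropped (eyes sit in the front
    half of the plane), as are implausibly small or large components (noise
    specks / CSF sheets) before the quadratic-cost Hausdorff scoring.
    """
    slice_2d = np.asarray(slice_2d, dtype=np.float64)
    spacing = np.asarray(spacing, dtype=np.float64)
    labels = measure.label(slice_2d >= T, connectivity=2)
    ny = slice_2d.shape[1]
    pixel_area = float(spacing[0] * spacing[1])
    out: list[EyeCandidate] = []
    for lab in range(1, labels.max() + 1):
        idx = np.argwhere(labels == lab)
        area = idx.shape[0] * pixel_area
        anterior = float((idx[:, 1] >= ny / 2).mean())
        if anterior < 0.5:
            continue
        if not (min_area_mm2 <= area <= max_area_mm2):
            log.debug("dropping candidate %d: area %.0f mm2 outside bounds", lab, area)
            continue
        pix_mm = idx * spacing[None, :]
        out.append(
            EyeCandidate(
                label=lab,
                indices=idx,
                pixels_mm=pix_mm,
                centroid_mm=pix_mm.mean(axis=0),
                anterior_fraction=anterior,
                area_mm2=area,
            )
        )
    return out


def hausdorff_circle_score(
    cand: EyeCandidate, diameter_mm: float = 20.0, spacing=(1.0, 1.0)
) -> float:
    """Bidirectional Hausdorff distance to a filled disk model.

    HD(A, B) = max{h(A,B), h(B,A)} between the candidate's filled point set
    and a filled disk of the given diameter rasterized on the same voxel
    lattice and centered at the candidate centroid (centering makes the score
    translation-invariant).  A perfect disk of matching size scores ≈ 0; a
    half-size disk scores the radius difference.
    """
    if cand.pixels_mm.shape[0] == 0:
        raise ValidationError("empty candidate point set")
    spacing = np.asarray(spacing, dtype=np.float64)
    r = diameter_mm / 2.0
    # rasterize the disk on the candidate's lattice
    c_idx = cand.centroid_mm / spacing
    half = np.ceil(r / spacing).astype(int) + 1
    xs = np.arange(int(np.floor(c_idx[0])) - half[0], int(np.ceil(c_idx[0])) + half[0] + 1)
    ys = np.arange(int(np.floor(c_idx[1])) - half[1], int(np.ceil(c_idx[1])) + half[1] + 1)
    gx, gy = np.meshgrid(xs, ys, indexing="ij")
    pts = np.stack([gx.ravel(), gy.ravel()], axis=1) * spacing[None, :]
    disk = pts[np.linalg.norm(pts - cand.centroid_mm[None, :], axis=1) <= r]
    a, b = cand.pixels_mm, disk
    hd = max(directed_hausdorff(a, b)[0], directed_hausdorff(b, a)[0])
    cand.hausdorff_mm = float(hd)
    return float(hd)


def select_and_remove_eyes(
    mask: BinaryMask,
    cands: list[EyeCandidate],
    max_eyes: int = 2,
    accept_mm: float = 5.0,
    diameter_mm: float = 20.0,
    spacing=(1.0, 1.0),
) -> BinaryMask:
    """Subtract the best-matching (≤ max_eyes) eye candidates from a mask.

    Candidates with Hausdorff score ≤ accept_mm are ranked by score; the
    winners' pixels, dilated by one voxel for a safety margin, are removed.
    Removal is purely subtractive: the output is a subset of the input.
    """
    scored = []
    for cand in cands:
        if cand.hausdorff_mm is None:
            hausdorff_circle_score(cand, diameter_mm=diameter_mm, spacing=spacing)
        if cand.hausdorff_mm <= accept_mm:
            scored.append(cand)
    scored.sort(key=lambda c: c.hausdorff_mm)
    out = mask.data.copy()
    for cand in scored[:max_eyes]:
        stamp = np.zeros(mask.data.shape, dtype=bool)
        stamp[cand.indices[:, 0], cand.indices[:, 1]] = True
        stamp = morphology.dilation(stamp, morphology.disk(1))
        out &= ~stamp
    return BinaryMask(data=out)
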