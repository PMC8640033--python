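"""End-to-end brain extraction: preprocess → background removal → FCM rough
mask → center-outward refinement sweep → morphological cleanup → eye removal.

The sweep starts at the center axial slice (which has no neighbor and gets
morphological cleanup only) and moves superior then inferior, each slice
using its already-refined neighbor for the refinement step.  Eye removal runs
after the sweep so the neighbor propagation is independent of eye detection.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from . import eye_removal, fcm, histogram_partition, preprocess, refine
from .config import PipelineConfig
from .errors import ValidationError
from .volume_io import BinaryMask, Volume

log = logging.getLogger(__name__)


@dataclass
class SliceRecord:
    """Intermediate quantities for one axial slice (for logging/inspection)."""

    index: int
    L: float | None = None
    thresholds: list | None = None
    fcm_iterations: int | None = None
    fallback: str | None = None
    eye_candidates: int = 0
    eyes_removed: int = 0


@dataclass
class ExtractionReport:
    """Per-slice processing log plus eye-stage summary."""

    slices: dict = field(default_factory=dict)
    eye_start_index: int | None = None
    eye_threshold: float | None = None
    center_slice: int | None = None


def preprocess_volume(v: Volume, config: PipelineConfig) -> Volume:
    """(Optional) bias correction → LPF → anisotropic diffusion."""
    out = v
    if config.bias.enabled:
        out = preprocess.bias_correct(out, sigma_mm=config.bias.sigma_mm)
    if config.lpf.enabled:
        out = preprocess.lowpass_filter(out, kernel_size=config.lpf.kernel)
    if config.adf.enabled:
        params = preprocess.ADFParams(
            iterations=config.adf.iterations,
            kappa=config.adf.kappa,
            lambda_=config.adf.lambda_,
            conductance_model=config.adf.model,
        )
        out = preprocess.anisotropic_diffusion(out, params)
    return out


def _background_stack(v: Volume, config: PipelineConfig, report: ExtractionReport) -> BinaryMask:
    """Per-slice (or volume-level) background removal over the whole stack."""
    nz = v.shape[2]
    bg = np.zeros(v.shape, dtype=bool)
    if config.hist.per_slice:
        for k in range(nz):
            m, L = histogram_partition.slice_background_mask(
                v.data[:, :, k],
                search_window_alphas=config.hist.search_window_alphas,
                range_max=config.hist.range_max,
            )
            bg[:, :, k] = m.data
            report.slices.setdefault(k, SliceRecord(index=k)).L = L
    else:
        m, L = histogram_partition.slice_background_mask(
            v.data.reshape(v.shape[0], -1),
            search_window_alphas=config.hist.search_window_alphas,
            range_max=config.hist.range_max,
        )
        bg = m.data.reshape(v.shape)
        for k in range(nz):
            report.slices.setdefault(k, SliceRecord(index=k)).L = L
    return BinaryMask(data=bg, affine=v.affine.copy())


def _process_slice(
    v: Volume,
    bg: BinaryMask,
    k: int,
    prev: BinaryMask | None,
    config: PipelineConfig,
    report: ExtractionReport,
) -> BinaryMask:
    rec = report.slices.setdefault(k, SliceRecord(index=k))
    slice_2d = v.data[:, :, k]
    bg_2d = BinaryMask(data=bg.data[:, :, k])
    if not bg_2d.data.any():
        return BinaryMask(data=np.zeros(slice_2d.shape, dtype=bool))
    try:
        rough, info = fcm.slice_rough_mask(
            slice_2d,
            bg_2d,
            c=config.fcm.clusters,
            m=config.fcm.mask_index,
            p=config.fcm.fuzziness,
            epsilon=config.fcm.epsilon,
            max_iter=config.fcm.max_iter,
        )
        rec.thresholds = info.get("thresholds")
        rec.fcm_iterations = info.get("iterations")
        rec.fallback = info.get("fallback")
    except Exception as exc:  # per-slice fallback rather than global abort
        log.warning("slice %d: FCM stage failed (%s); using background mask", k, exc)
        rec.fallback = f"error:{exc}"
        rough = BinaryMask(data=bg_2d.data.copy())
    combined = refine.refine_with_previous(rough, bg_2d, prev)
    return refine.morphological_cleanup(combined)


def _apply_eye_removal(
    v: Volume,
    bg: BinaryMask,
    mask3d: np.ndarray,
    config: PipelineConfig,
    report: ExtractionReport,
) -> None:
    T = eye_removal.eye_intensity_threshold(
        v, mask=bg.data, percentile=config.eyes.percentile
    )
    report.eye_threshold = T
    start = eye_removal.locate_eye_start(v, bg, offset_mm=config.eyes.offset_mm)
    report.eye_start_index = start
    if start is None:
        return
    spacing2d = (v.spacing[0], v.spacing[1])
    for k in range(start, -1, -1):  # from the start index toward the inferior end
        rec = report.slices.setdefault(k, SliceRecord(index=k))
        cands = eye_removal.eye_candidates(v.data[:, :, k], T, spacing=spacing2d)
        rec.eye_candidates = len(cands)
        if not cands:
            continue
        before = mask3d[:, :, k].sum()
        cleaned = eye_removal.select_and_remove_eyes(
            BinaryMask(data=mask3d[:, :, k]),
            cands,
            max_eyes=config.eyes.max_eyes,
            accept_mm=config.eyes.accept_mm,
            diameter_mm=config.eyes.diameter_mm,
            spacing=spacing2d,
        )
        mask3d[:, :, k] = cleaned.data
        rec.eyes_removed = sum(
            1 for c in cands if c.hausdorff_mm is not None and c.hausdorff_mm <= config.eyes.accept_mm
        )
        if before != mask3d[:, :, k].sum():
            log.debug("slice %d: removed %d eye voxels", k, before - mask3d[:, :, k].sum())


def extract_brain(
    v: Volume,
    config: PipelineConfig | None = None,
    return_report: bool = False,
):
    """Extract the 3D brain mask from a preprocessable RAS volume.

    The volume is preprocessed, background-removed per slice, rough-masked by
    FCM thresholding, refined center-outward and cleaned morphologically;
    slices whose background mask is empty yield empty brain masks.  Eye
    removal applies afterwards from the detected start index inferior-ward.
    """
    config = config or PipelineConfig()
    if v.orientation != "RAS":
        raise ValidationError("extract_brain expects an RAS volume; reorient first")
    report = ExtractionReport()

    if not (v.data > 0).any():
        log.warning("volume has no positive voxels; returning empty mask")
        empty = BinaryMask(data=np.zeros(v.shape, dtype=bool), affine=v.affine.copy())
        return (empty, report) if return_report else empty

    pre = preprocess_volume(v, config)
    bg = _background_stack(pre, config, report)

    out = np.zeros(v.shape, dtype=bool)
    occupied = np.nonzero(bg.data.any(axis=(0, 1)))[0]
    if occupied.size == 0:
        log.warning("no foreground in any slice; returning empty mask")
        empty = BinaryMask(data=out, affine=v.affine.copy())
        return (empty, report) if return_report else empty

    center = int((occupied[0] + occupied[-1]) // 2)
    report.center_slice = center

    center_mask = _process_slice(pre, bg, center, None, config, report)
    out[:, :, center] = center_mask.data
    prev = center_mask
    for k in range(center + 1, v.shape[2]):  # superior sweep
        cur = _process_slice(pre, bg, k, prev, config, report)
        out[:, :, k] = cur.data
        prev = cur
    prev = center_mask
    for k in range(center - 1, -1, -1):      # inferior sweep
        cur = _process_slice(pre, bg, k, prev, config, report)
        out[:, :, k] = cur.data
        prev = cur

    if config.eyes.enabled:
        try:
            _apply_eye_removal(pre, bg, out, config, report)
        except Exception as exc:
            log.warning("eye removal failed (%s); mask left unchanged", exc)

    result = BinaryMask(data=out, affine=v.affine.copy())
    return (result, report) if return_report else result
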