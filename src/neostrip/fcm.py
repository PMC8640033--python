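"""Fuzzy c-means clustering of slice intensities and threshold derivation.

FCM minimizes the membership-weighted sum-of-squares error
SSE = Σ_i Σ_j ω_ij^p d(x_i, c_j)², alternating the membership update
ω_ij = 1 / Σ_k (d_ij/d_ik)^(2/(p−1)) with the centroid update
c_j = Σ_i ω_ij^p x_i / Σ_i ω_ij^p.  The distance d is 1D absolute intensity
difference.  Hard-assigning each element to its maximum-membership cluster
gives cluster intensity sets I_m, and the inter-cluster thresholds
th_m = (max(I_m) + min(I_{m+1})) / 2 produce a family of nested bright-side
masks; mask #2 of 7 clusters is the rough brain mask for T2w infant images
(mask #1 keeps too much dark non-brain tissue, higher masks too little brain).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .errors import DataError, EmptyClusterError, ParameterError
from .volume_io import BinaryMask

log = logging.getLogger(__name__)


@dataclass
class FCMModel:
    """Converged fuzzy c-means state with centroids sorted ascending."""

    centroids: np.ndarray          # (c,) ascending
    membership: np.ndarray         # (n, c), rows sum to 1
    fuzziness: float
    epsilon: float
    sse_trace: list[float] = field(default_factory=list)
    thresholds: np.ndarray | None = None  # (c-1,), set by cluster_thresholds

    @property
    def n_clusters(self) -> int:
        return len(self.centroids)


def _quantile_init(values: np.ndarray, c: int) -> np.ndarray:
    """Deterministic init: centroids at the (2j−1)/(2c) quantiles, j = 1…c."""
    q = (2 * np.arange(1, c + 1) - 1) / (2 * c)
    cent = np.quantile(values, q)
    # coincident quantiles (heavily repeated values) would never separate;
    # nudge ties apart deterministically
    for j in range(1, c):
        if cent[j] <= cent[j - 1]:
            cent[j] = cent[j - 1] + 1e-6 * max(1.0, abs(cent[j - 1]))
    return cent


def _memberships(values: np.ndarray, centroids: np.ndarray, p: float) -> np.ndarray:
    d2 = (values[:, None] - centroids[None, :]) ** 2
    hit = (d2 < 1e-300).any(axis=1)
    safe = np.where(d2 < 1e-300, 1.0, d2)
    w = safe ** (-1.0 / (p - 1.0))
    omega = w / w.sum(axis=1, keepdims=True)
    if hit.any():
        # singularity rule: an element coincident with a centroid belongs to
        # the nearest centroid with membership 1
        omega[hit] = 0.0
        omega[hit, np.argmin(d2[hit], axis=1)] = 1.0
    return omega


def fcm_fit(
    values,
    c: int = 7,
    p: float = 2.0,
    epsilon: float = 0.02,
    max_iter: int = 100,
    init: str = "quantile",
    seed: int | None = None,
) -> FCMModel:
    """Fit 1D fuzzy c-means to a collection of intensities.

    Termination: relative SSE decrease |SSE_t − SSE_{t−1}| / SSE_{t−1} < ε
    (the stated stopping rule "min SSE < ε" is read as a relative-change
    criterion since absolute SSE scales with the data).  The default
    quantile initialization needs no randomness; ``init="random"`` draws
    initial centroids from the data using ``seed``.
    """
    values = np.asarray(values, dtype=np.float64).ravel()
    if c < 2:
        raise ParameterError("need at least 2 clusters")
    if p <= 1:
        raise ParameterError("fuzziness p must be > 1")
    if values.size < c:
        raise DataError(f"{values.size} values for {c} clusters")
    if (values < 0).any():
        raise DataError("negative intensities not allowed")

    if init == "quantile":
        centroids = _quantile_init(values, c)
    elif init == "random":
        rng = np.random.default_rng(seed)
        centroids = np.sort(rng.choice(values, size=c, replace=False))
    else:
        raise ParameterError(f"unknown init {init!r}")

    sse_trace: list[float] = []
    omega = _memberships(values, centroids, p)
    for _ in range(max_iter):
        wp = omega ** p
        denom = wp.sum(axis=0)
        # a cluster with vanishing total membership keeps its centroid
        newc = np.where(denom > 1e-300, (wp * values[:, None]).sum(axis=0) / np.maximum(denom, 1e-300), centroids)
        centroids = newc
        omega = _memberships(values, centroids, p)
        d2 = (values[:, None] - centroids[None, :]) ** 2
        sse = float(((omega ** p) * d2).sum())
        sse_trace.append(sse)
        if len(sse_trace) >= 2:
            prev = sse_trace[-2]
            if prev > 0 and abs(prev - sse) / prev < epsilon:
                break

    order = np.argsort(centroids)
    return FCMModel(
        centroids=centroids[order],
        membership=omega[:, order],
        fuzziness=p,
        epsilon=epsilon,
        sse_trace=sse_trace,
    )


def hard_assignments(model: FCMModel) -> np.ndarray:
    """Index of the maximum-membership cluster for each element."""
    return np.argmax(model.membership, axis=1)


def cluster_thresholds(model: FCMModel, values) -> np.ndarray:
    """Inter-cluster thresholds th_m = (max(I_m) + min(I_{m+1})) / 2.

    Clusters are ordered by centroid; I_m is the intensity set of elements
    hard-assigned to cluster m.  Raises EmptyClusterError if any cluster
    received no elements.
    """
    values = np.asarray(values, dtype=np.float64).ravel()
    if values.size != model.membership.shape[0]:
        raise DataError("values do not match the fitted membership matrix")
    labels = hard_assignments(model)
    c = model.n_clusters
    maxs = np.empty(c)
    mins = np.empty(c)
    for j in range(c):
        sel = values[labels == j]
        if sel.size == 0:
            raise EmptyClusterError(j)
        maxs[j] = sel.max()
        mins[j] = sel.min()
    th = (maxs[:-1] + mins[1:]) / 2.0
    model.thresholds = th
    return th


def rough_mask(slice_2d: np.ndarray, bg: BinaryMask, thresholds, m: int = 2) -> BinaryMask:
    """Mask #m: voxels inside the background mask with intensity ≥ th_m.

    Masks are nested: mask #m ⊇ mask #(m+1).
    """
    thresholds = np.asarray(thresholds, dtype=np.float64)
    if not (1 <= m <= len(thresholds)):
        raise ParameterError(f"mask index {m} outside 1..{len(thresholds)}")
    slice_2d = np.asarray(slice_2d, dtype=np.float64)
    if slice_2d.shape != bg.data.shape:
        raise DataError("slice and background mask shapes differ")
    return BinaryMask(data=bg.data & (slice_2d >= thresholds[m - 1]))


def slice_rough_mask(
    slice_2d: np.ndarray,
    bg: BinaryMask,
    c: int = 7,
    m: int = 2,
    p: float = 2.0,
    epsilon: float = 0.02,
    max_iter: int = 100,
) -> tuple[BinaryMask, dict]:
    """Fit FCM on the background-interior intensities and build mask #m.

    Fallbacks: fewer than c distinct intensities → FCM skipped and the
    background mask itself is returned; an empty cluster → one retry with
    c − 1 clusters (m capped accordingly), then the same background fallback.
    Returns (mask, info) where info records thresholds/iterations/fallbacks.
    """
    vals = np.asarray(slice_2d, dtype=np.float64)[bg.data]
    info: dict = {"fallback": None, "c": c, "m": m}
    if np.unique(vals).size < c:
        info["fallback"] = "too-few-distinct-intensities"
        log.info("rough mask fallback (%s)", info["fallback"])
        return BinaryMask(data=bg.data.copy()), info
    for attempt_c in (c, c - 1):
        try:
            model = fcm_fit(vals, c=attempt_c, p=p, epsilon=epsilon, max_iter=max_iter)
            th = cluster_thresholds(model, vals)
            mm = min(m, attempt_c - 1)
            info.update(c=attempt_c, m=mm, thresholds=th.tolist(),
                        iterations=len(model.sse_trace))
            return rough_mask(slice_2d, bg, th, m=mm), info
        except EmptyClusterError as exc:
            info["fallback"] = f"empty-cluster-{exc.index}-at-c{attempt_c}"
            log.info("rough mask retry (%s)", info["fallback"])
            continue
    log.info("rough mask fallback to background mask")
    return BinaryMask(data=bg.data.copy()), info
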