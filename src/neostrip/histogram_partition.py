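"""Background removal by Gaussian-matched histogram partitioning.

An MR slice histogram H(x) shows the dark air background and the head as
separate mass concentrations.  A Gaussian P(x) with the same mean μ, standard
deviation α and area as H(x) is convex where H has its inter-mode valley, so
the intensity of maximum divergence P(x) − H(x) near μ estimates the valley
and serves as the background threshold L.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .errors import DegenerateHistogramError, ParameterError
from .volume_io import BinaryMask

log = logging.getLogger(__name__)

#: intensities are rescaled to this range before histogramming (bin width 1)
DEFAULT_RANGE_MAX = 255


@dataclass
class IntensityHistogram:
    """Integer-width intensity histogram with its first two moments.

    Bins run from x_min = 0 to x_max = the highest intensity present; mu and
    alpha are computed from the raw values, not the binned counts.
    """

    bin_centers: np.ndarray
    counts: np.ndarray
    mu: float
    alpha: float

    @property
    def area(self) -> float:
        return float(self.counts.sum())


@dataclass
class MatchedGaussian:
    """Gaussian P(x) sharing mean, SD and area with a histogram."""

    values: np.ndarray
    z: float
    scale: float


def build_histogram(values, bin_width: float = 1.0) -> IntensityHistogram:
    """Histogram non-negative intensities into integer-width bins from 0.

    Raises for a zero-spread input: with α = 0 no matched Gaussian exists.
    """
    values = np.asarray(values, dtype=np.float64).ravel()
    if values.size < 2 or np.unique(values).size < 2:
        raise DegenerateHistogramError("need at least 2 distinct values")
    if bin_width <= 0:
        raise ParameterError("bin_width must be positive")
    idx = np.round(values / bin_width).astype(np.int64)
    counts = np.bincount(idx)
    centers = np.arange(counts.size, dtype=np.float64) * bin_width
    mu = float(values.mean())
    alpha = float(values.std())
    if alpha == 0:
        raise DegenerateHistogramError("zero intensity spread")
    return IntensityHistogram(bin_centers=centers, counts=counts.astype(np.float64),
                              mu=mu, alpha=alpha)


def matched_gaussian(h: IntensityHistogram) -> MatchedGaussian:
    """P(x) = (area/z)·G((x−μ)/α), normalized so Σ P equals the histogram area."""
    if h.alpha <= 0:
        raise DegenerateHistogramError("alpha must be > 0")
    g = np.exp(-0.5 * ((h.bin_centers - h.mu) / h.alpha) ** 2)
    z = float(g.sum())
    scale = h.area / z
    return MatchedGaussian(values=scale * g, z=z, scale=scale)


def partition_threshold(
    h: IntensityHistogram, g: MatchedGaussian, search_window_alphas: float = 2.0
) -> float:
    """Valley threshold L = argmax_x (P(x) − H(x)) within |x − μ| ≤ wα.

    The window keeps the argmax near the mean, where the Gaussian's convexity
    contrasts with the inter-mode concavity; ties break toward the smallest x
    (keeping more tissue — later stages correct errors of inclusion).  The
    search is additionally restricted to intensities above the background
    peak (the dominant bin at or below the mean): a "valley" below the
    background peak would not separate anything, but P − H can still peak
    there because H vanishes below the background mode.
    """
    if search_window_alphas <= 0:
        raise ParameterError("search_window_alphas must be > 0")
    in_window = np.abs(h.bin_centers - h.mu) <= search_window_alphas * h.alpha
    if not in_window.any():
        raise ParameterError("empty search window")
    low = h.bin_centers <= h.mu
    if low.any():
        mode_x = h.bin_centers[low][int(np.argmax(h.counts[low]))]
        above_mode = h.bin_centers > mode_x
        if (in_window & above_mode).any():
            in_window &= above_mode
    diff = np.where(in_window, g.values - h.counts, -np.inf)
    return float(h.bin_centers[int(np.argmax(diff))])  # argmax -> first (smallest x)


def background_mask(slice_2d: np.ndarray, L: float) -> BinaryMask:
    """Object mask of a slice: voxels with intensity ≥ L."""
    slice_2d = np.asarray(slice_2d, dtype=np.float64)
    return BinaryMask(data=slice_2d >= L)


def slice_background_mask(
    slice_2d: np.ndarray,
    search_window_alphas: float = 2.0,
    range_max: int = DEFAULT_RANGE_MAX,
) -> tuple[BinaryMask, float]:
    """Full per-slice background removal; returns (mask, L in original units).

    Intensities are scaled to 0…range_max for histogram stability (unit bins
    on a uint8-like range) and the threshold is mapped back afterwards.
    Slices with no usable spread (empty or constant) yield an empty mask.
    """
    slice_2d = np.asarray(slice_2d, dtype=np.float64)
    vmax = slice_2d.max()
    if vmax <= 0:
        return BinaryMask(data=np.zeros(slice_2d.shape, dtype=bool)), np.inf
    scale = range_max / vmax
    scaled = slice_2d * scale
    vals = scaled[scaled > 0]
    try:
        h = build_histogram(vals)
        g = matched_gaussian(h)
        L_scaled = partition_threshold(h, g, search_window_alphas)
    except DegenerateHistogramError:
        log.info("degenerate slice histogram; returning empty background mask")
        return BinaryMask(data=np.zeros(slice_2d.shape, dtype=bool)), np.inf
    L = L_scaled / scale
    return background_mask(slice_2d, L), L
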