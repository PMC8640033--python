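"""Denoising and simplified inhomogeneity correction.

All filters operate per axial slice (2D), matching the slice-by-slice design
of the extraction pipeline and its 3×3 (not 3×3×3) kernels.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage import filters

from .errors import ParameterError, ValidationError
from .volume_io import Volume

log = logging.getLogger(__name__)


@dataclass
class ADFParams:
    """Anisotropic (Perona–Malik) diffusion parameters.

    kappa is the gradient-conductance constant in intensity units; ``None``
    selects 10% of each slice's 99th-percentile intensity.  lambda_ is the
    explicit update step, stable for 4-neighbour 2D diffusion when ≤ 0.25.
    """

    iterations: int = 5
    kappa: float | None = None
    lambda_: float = 0.2
    conductance_model: str = "exponential"

    def __post_init__(self):
        if self.iterations < 1:
            raise ParameterError("iterations must be >= 1")
        if not (0 < self.lambda_ <= 0.25):
            raise ParameterError("lambda must be in (0, 0.25]")
        if self.kappa is not None and self.kappa <= 0:
            raise ParameterError("kappa must be > 0")
        if self.conductance_model not in ("exponential", "rational"):
            raise ParameterError(f"unknown conductance model {self.conductance_model!r}")


def lowpass_filter(v: Volume, kernel_size: int = 3) -> Volume:
    """Per-slice mean filter with edge replication.

    A small (default 3×3) kernel is used so fine structure survives; the
    filter exists to suppress pixel noise before histogram partitioning.
    """
    if kernel_size % 2 == 0 or kernel_size < 3:
        raise ParameterError("kernel_size must be odd and >= 3")
    out = ndimage.uniform_filter(
        v.data, size=(kernel_size, kernel_size, 1), mode="nearest"
    )
    return v.copy_with(out)


def _diffuse_slice_stack(data: np.ndarray, params: ADFParams, kappa: np.ndarray) -> np.ndarray:
    """Explicit Perona–Malik diffusion on every axial slice at once.

    I_{t+1} = I_t + λ Σ_{4-neighbours} g(∇I)·∇I, with ∇I the one-sided
    difference toward each in-plane neighbour and g the conductance.
    kappa is broadcastable over slices (shape (1,1,nz)).
    """
    out = data.copy()
    for _ in range(params.iterations):
        dn = np.zeros_like(out)
        ds = np.zeros_like(out)
        de = np.zeros_like(out)
        dw = np.zeros_like(out)
        dn[1:, :, :] = out[:-1, :, :] - out[1:, :, :]
        ds[:-1, :, :] = out[1:, :, :] - out[:-1, :, :]
        de[:, 1:, :] = out[:, :-1, :] - out[:, 1:, :]
        dw[:, :-1, :] = out[:, 1:, :] - out[:, :-1, :]
        total = np.zeros_like(out)
        for d in (dn, ds, de, dw):
            s = d / kappa
            if params.conductance_model == "exponential":
                g = np.exp(-(s * s))
            else:
                g = 1.0 / (1.0 + s * s)
            total += g * d
        out += params.lambda_ * total
    return out


def anisotropic_diffusion(v: Volume, params: ADFParams | None = None) -> Volume:
    """Edge-preserving per-slice smoothing.

    Regions with rapid gradient change (|∇I| ≫ κ) conduct little and keep
    their edges; flat regions diffuse toward the local mean.
    """
    params = params or ADFParams()
    if params.kappa is None:
        p99 = np.percentile(v.data.reshape(-1, v.shape[2]), 99, axis=0)
        kappa = np.maximum(0.1 * p99, 1e-6)[None, None, :]
    else:
        kappa = np.full((1, 1, v.shape[2]), float(params.kappa))
    return v.copy_with(_diffuse_slice_stack(v.data, params, kappa))


def _foreground(data):
    """Head foreground: Otsu split of the positive voxels (air noise has a
    nonzero floor, so a plain positivity test would include the background)."""
    positive = data > 0
    try:
        fg = data > filters.threshold_otsu(data[positive])
    except ValueError:  # constant image
        fg = positive
    return fg if fg.any() else positive


def _poly_terms(shape, degree):
    """Polynomial basis evaluated on the full voxel grid (broadcast form)."""
    scalec = np.asarray(shape, float)
    x = (np.arange(shape[0]) / scalec[0])[:, None, None]
    y = (np.arange(shape[1]) / scalec[1])[None, :, None]
    z = (np.arange(shape[2]) / scalec[2])[None, None, :]
    terms = [np.ones(shape), x + 0 * y + 0 * z, y + 0 * x + 0 * z, z + 0 * x + 0 * y]
    if degree == 2:
        base = [x, y, z]
        terms += [base[i] * base[j] + np.zeros(shape)
                  for i in range(3) for j in range(i, 3)]
    return terms


def _iterative_poly_field(data, fg, degree, n_iter=4, band=0.20):
    """Multiplicative field as exp of a polynomial fit to the log intensity
    of the dominant tissue, iterated so the tissue selection is made on the
    partially corrected image (the raw selection is itself bias-corrupted).
    """
    shape = data.shape
    scalec = np.asarray(shape, float)
    terms = _poly_terms(shape, degree)
    logfield = np.zeros(shape)
    rng = np.random.default_rng(0)  # deterministic subsampling only
    for _ in range(n_iter):
        current = data / np.exp(logfield)
        med = np.median(current[fg])
        tissue = fg & (np.abs(current - med) <= band * med)
        # drop boundary voxels: partial-volume tails at tissue interfaces are
        # spatially one-sided and would masquerade as a bias bowl
        eroded = ndimage.binary_erosion(tissue, iterations=2)
        if eroded.sum() >= 1000:
            tissue = eroded
        elif tissue.sum() < 1000:
            tissue = fg
        idx = np.argwhere(tissue)
        if idx.shape[0] > 50_000:
            idx = idx[rng.choice(idx.shape[0], 50_000, replace=False)]
        pts = idx / scalec[None, :]
        cols = [np.ones(pts.shape[0])] + [pts[:, i] for i in range(3)]
        if degree == 2:
            cols += [pts[:, i] * pts[:, j] for i in range(3) for j in range(i, 3)]
        X = np.stack(cols, axis=1)
        yv = np.log(np.maximum(current[tuple(idx.T)], 1e-6))
        coef, *_ = np.linalg.lstsq(X, yv, rcond=None)
        logfield = logfield + sum(c * t for c, t in zip(coef, terms))
        logfield -= logfield[fg].mean()
    return np.exp(logfield)


def bias_correct(v: Volume, sigma_mm: float = 30.0, method: str = "polynomial",
                 degree: int = 2) -> Volume:
    """Homomorphic correction of smooth multiplicative intensity inhomogeneity.

    The log-intensity field over the head foreground is modeled by a
    low-order 3D polynomial (default degree 2) fit by least squares; the
    volume is divided by the exponentiated field and renormalized to preserve
    the mean foreground intensity.  A low-order polynomial captures the
    slowly varying coil-shading fields that produce multiplicative bias while
    staying nearly constant on unbiased anatomy.  ``method="gaussian"``
    instead divides by a broad masked-Gaussian estimate of the log field at
    scale ``sigma_mm``.  The stage is a deliberately simple surrogate with
    the same interface as a full N3/N4 correction and can be skipped for
    externally corrected input.
    """
    if v.data.ndim != 3:
        raise ValidationError("bias_correct expects a 3D volume")
    if method not in ("polynomial", "gaussian"):
        raise ParameterError(f"unknown bias method {method!r}")
    if degree not in (1, 2):
        raise ParameterError("polynomial degree must be 1 or 2")
    if not (v.data > 0).any():
        log.warning("bias_correct: all-zero volume, returning input unchanged")
        return v.copy_with(v.data.copy())
    fg = _foreground(v.data)

    if method == "gaussian":
        sigma_vox = np.asarray(sigma_mm) / np.asarray(v.spacing)
        logI = np.where(fg, np.log(np.maximum(v.data, 1e-6)), 0.0)
        num = ndimage.gaussian_filter(logI, sigma=sigma_vox)
        den = ndimage.gaussian_filter(fg.astype(np.float64), sigma=sigma_vox)
        # normalized convolution: the local mean log intensity inside the
        # head, extrapolated smoothly from the nearest tissue outside it
        field = np.exp(np.where(den > 1e-6, num / np.maximum(den, 1e-6), 0.0))
    else:
        field = _iterative_poly_field(v.data, fg, degree)

    corrected = v.data / field
    # preserve the mean foreground intensity
    scale = v.data[fg].mean() / max(corrected[fg].mean(), 1e-12)
    return v.copy_with(corrected * scale)
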