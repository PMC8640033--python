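"""Overlap metrics between an algorithm mask and a reference mask."""

from __future__ import annotations

import numpy as np

from .errors import GridMismatchError, UndefinedScoreError
from .volume_io import BinaryMask


def _as_bool(a) -> np.ndarray:
    if isinstance(a, BinaryMask):
        return a.data
    return np.asarray(a, dtype=bool)


def dice(a, b) -> float:
    """Dice coefficient 2|A∩B| / (|A| + |B|); symmetric, 1 iff A = B."""
    a, b = _as_bool(a), _as_bool(b)
    if a.shape != b.shape:
        raise GridMismatchError("masks must share a grid")
    na, nb = int(a.sum()), int(b.sum())
    if na + nb == 0:
        raise UndefinedScoreError("dice undefined for two empty masks")
    return 2.0 * int((a & b).sum()) / (na + nb)


def precision(detected, truth) -> float:
    """Fraction of detected voxels that are true: |D∩T| / |D|.

    Asymmetric: the first argument is the algorithm's detection, the second
    the reference.
    """
    d, t = _as_bool(detected), _as_bool(truth)
    if d.shape != t.shape:
        raise GridMismatchError("masks must share a grid")
    nd = int(d.sum())
    if nd == 0:
        raise UndefinedScoreError("precision undefined for an empty detection")
    return int((d & t).sum()) / nd


def per_slice_scores(detected, truth, axis: int = 2):
    """(dice, precision) per axial slice; None where a score is undefined."""
    d, t = _as_bool(detected), _as_bool(truth)
    if d.shape != t.shape:
        raise GridMismatchError("masks must share a grid")
    out = []
    for k in range(d.shape[axis]):
        ds = np.take(d, k, axis=axis)
        ts = np.take(t, k, axis=axis)
        try:
            dv = dice(ds, ts)
        except UndefinedScoreError:
            dv = None
        try:
            pv = precision(ds, ts)
        except UndefinedScoreError:
            pv = None
        out.append((dv, pv))
    return out
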