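import numpy as np
import pytest

from neostrip.config import PipelineConfig
from neostrip.phantom import PhantomSpec, generate_phantom
from neostrip.pipeline import extract_brain


@pytest.fixture(scope="session")
def default_phantom():
    """Default seeded phantom: (volume, truth_brain, truth_eyes)."""
    return generate_phantom(PhantomSpec())


@pytest.fixture(scope="session")
def preprocessed_phantom(default_phantom):
    """(preprocessed volume, truth_brain) — the input the per-slice stages see."""
    from neostrip.pipeline import preprocess_volume

    vol, truth_brain, _ = default_phantom
    return preprocess_volume(vol, PipelineConfig()), truth_brain


@pytest.fixture(scope="session")
def phantom_extraction(default_phantom):
    """Full pipeline runs on the default phantom, shared across tests.

    Returns a dict with two independent default runs (for determinism
    checks), a run with eye removal disabled, and the processing report.
    """
    vol, truth_brain, truth_eyes = default_phantom
    mask1, report = extract_brain(vol, return_report=True)
    mask2 = extract_brain(vol)
    cfg = PipelineConfig()
    cfg.eyes.enabled = False
    mask_noeyes = extract_brain(vol, cfg)
    return {
        "volume": vol,
        "truth_brain": truth_brain,
        "truth_eyes": truth_eyes,
        "mask": mask1,
        "mask_repeat": mask2,
        "mask_noeyes": mask_noeyes,
        "report": report,
    }


def reference_fcm(values, c, p=2.0, epsilon=1e-9, max_iter=5000):
    """Plain-loop reference fuzzy c-means with quantile initialization.

    Deliberately naive (per-element loops, no vectorized shortcuts) so it is
    an independent oracle for the packaged implementation.
    """
    values = np.asarray(values, dtype=float).ravel()
    n = len(values)
    q = (2 * np.arange(1, c + 1) - 1) / (2 * c)
    cent = np.quantile(values, q)
    for j in range(1, c):
        if cent[j] <= cent[j - 1]:
            cent[j] = cent[j - 1] + 1e-6 * max(1.0, abs(cent[j - 1]))
    prev_sse = None
    for _ in range(max_iter):
        w = np.zeros((n, c))
        for i in range(n):
            d2 = (values[i] - cent) ** 2
            if (d2 < 1e-300).any():
                w[i, int(np.argmin(d2))] = 1.0
                continue
            inv = d2 ** (-1.0 / (p - 1.0))
            w[i] = inv / inv.sum()
        for j in range(c):
            wp = w[:, j] ** p
            if wp.sum() > 0:
                cent[j] = (wp * values).sum() / wp.sum()
        sse = 0.0
        for i in range(n):
            sse += ((w[i] ** p) * (values[i] - cent) ** 2).sum()
        if prev_sse is not None and prev_sse > 0 and abs(prev_sse - sse) / prev_sse < epsilon:
            break
        prev_sse = sse
    order = np.argsort(cent)
    return cent[order], w[:, order]
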