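"""Fuzzy c-means thresholding of one slice: centroids, thresholds, mask #2.

FCM with 7 clusters partitions the background-removed intensities; the
inter-cluster thresholds th_m = (max(I_m) + min(I_{m+1}))/2 define nested
bright-side masks, and mask #2 is the rough brain mask.
"""

import numpy as np

from neostrip import PhantomSpec, generate_phantom
from neostrip.config import PipelineConfig
from neostrip.fcm import cluster_thresholds, fcm_fit, rough_mask
from neostrip.histogram_partition import slice_background_mask
from neostrip.pipeline import preprocess_volume

volume, truth_brain, _ = generate_phantom(PhantomSpec(seed=0))
pre = preprocess_volume(volume, PipelineConfig())
k = pre.shape[2] // 2
slice_2d = pre.data[:, :, k]
bg, L = slice_background_mask(slice_2d)

values = slice_2d[bg.data]
model = fcm_fit(values, c=7)
th = cluster_thresholds(model, values)

print(f"slice z={k}: background threshold L = {L:.1f}, "
      f"{bg.count()} voxels enter FCM")
print("centroids:", np.round(model.centroids, 1))
print("thresholds th_1..th_6:", np.round(th, 1))
print(f"converged in {len(model.sse_trace)} iterations "
      f"(relative SSE change < {model.epsilon})")

m2 = rough_mask(slice_2d, bg, th, m=2)
print(f"rough brain mask (#2): {m2.count()} voxels")

# th_2 falls below the brain-tissue intensity bulk, so mask #2 keeps brain,
# CSF and scalp while dropping the dark dura/muscle fringe; the scalp ring
# and any interior holes are handled by the morphological cleanup stage.
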