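# Methods

This note documents the model behind `neostrip`, the parameter choices, the
synthetic phantom used for validation, and the known limitations.

## The extraction model

The pipeline treats skull stripping of infant T2-weighted volumes as a
slice-by-slice segmentation problem with three intensity regimes: a dark
background regime (air, cortical bone, dura — all near the noise floor in
T2w), a mid-bright brain regime (white/gray matter; in infants under ~6
months WM is brighter than GM), and a bright regime (CSF, subcutaneous fat,
eyeballs). The stages exploit this ordering:

**Background removal.** For each axial slice the intensity histogram H(x)
is built over unit-width bins from 0 to the maximum (intensities are
rescaled to 0–255 internally for bin stability). A Gaussian
P(x) = (area/z)·G((x−μ)/α) shares H's mean μ, standard deviation α and
area. Where H is bimodal, P is convex over the inter-mode valley, so
L = argmax (P − H) estimates the valley intensity. Two restrictions make
the argmax robust: the search stays within |x − μ| ≤ 2α of the mean (the
window width is configurable; divergence far in the tails is spurious), and
it stays above the dominant histogram peak at or below μ — below the
background peak H vanishes, so P − H can peak there without separating
anything. Ties break toward the smallest x, keeping more tissue; later
stages correct inclusion errors. Slices with no usable spread yield empty
masks.

With T2w-like intensities the valley lands in the empty stretch between the
dark regime and the brain, so the background-removed mask holds the
*bright* head tissues (brain, CSF, scalp/fat, eyes) and discards air along
with the bone/dura shells. This matters downstream: the refinement step can
only track a shrinking brain outline if the tissue immediately outside the
mask boundary is excluded from the background mask (see Refinement).

**Rough mask by fuzzy c-means.** FCM with c = 7 clusters, fuzziness p = 2
and termination threshold ε = 0.02 runs on the background-interior
intensities of each slice. The objective is
SSE = Σᵢ Σⱼ ωᵢⱼᵖ d(xᵢ, cⱼ)², with d the absolute intensity difference,
memberships ωᵢⱼ = 1/Σₖ (dᵢⱼ/dᵢₖ)^{2/(p−1)} and centroids the
membership-weighted means. The stopping rule "min SSE < ε" is read as a
*relative* SSE decrease below ε, since absolute SSE scales with the data.
Initialization is deterministic: centroids at the (2j−1)/(2c) quantiles, so
the whole pipeline needs no random seed. An element coinciding with a
centroid gets membership 1 there (the standard singularity rule). After
hard assignment, th_m = (max(I_m)+min(I_{m+1}))/2 and mask #m keeps
intensities ≥ th_m; masks are therefore nested in m. Mask #2 drops the
darkest two clusters — residual dark fringe (partial-volume and
dura/muscle remnants that survive background removal) — and keeps brain,
CSF and scalp. Fallbacks: fewer distinct intensities than clusters, or an
empty cluster after a retry with c−1, degrade gracefully to the background
mask for that slice.

Note that th₂ frequently falls inside the lower tail of the brain-intensity
distribution. This is harmless: the bright CSF rim encloses the brain in
every axial slice, so the hole-filling step of the cleanup restores any
interior sub-threshold region. What matters is that th₂ stays below the
CSF/scalp intensities (so the enclosing rim is intact) and above the dark
fringe.

**Refinement.** Processing starts at the center slice of the occupied
axial range, which gets morphological cleanup only, and sweeps superior
then inferior, each slice using its already-refined neighbor `prev`:

    diff     = bg AND NOT rough      (candidate missing regions)
    missing  = diff AND prev         (confirmed by the neighbor)
    kept     = rough AND NOT diff    (≡ rough; evaluated as stated)
    combined = missing OR kept

`kept` is algebraically identical to `rough`; the formula is evaluated
literally and the equivalence is covered by tests. Cleanup is erosion,
largest 8-connected component, dilation (3×3 disk ≡ radius-1 cross — the
2D reading of a "spherical" element), then hole filling. The refinement is
purely additive (combined ⊇ rough, combined ⊆ rough ∪ (bg ∩ prev)), which
has a structural consequence: any tissue ring that is inside the background
mask and under the previous slice's footprint is re-added forever, so the
mask can only shrink through tissue the background mask excludes. With the
dark bone/dura shells excluded (see above) the sweep tracks the shrinking
brain correctly; the residual cost is a ~1-voxel halo at the bright rim
(created by the 3×3 mean filter mixing rim intensity into the first
outside voxel) that the mask inherits from the background contour.

**Eye removal.** Runs after the sweep, so neighbor propagation is
independent of eye detection. The slice range is found geometrically: the
sagittal slice with the longest anterior–posterior extent of the
background stack, a line 15 mm posterior of its front-most occupied column
(skull thickness plus eye radius), the coronal slice through that line,
and a left–right projection of its background-masked intensities. A
Gaussian matched to the projection (same construction as in background
removal) is subtracted; the superior–inferior argmax of the divergence is
the starting axial index, and removal applies from there toward the
inferior end. If the peak divergence is below 1.5 % of the projection area
the stage disables itself (an eyeless head measures ~0.5 %, a 20 mm eye
pair ~2.7 %; masking the projection by the background stack keeps the air
baseline from diluting the peak). Candidates per slice are 8-connected
components above the 60th percentile of head intensities (the white/gray
matter bulk is ~60 % of the head histogram in young infants, so this
keeps CSF, fat and eyes), restricted to the anterior half of the plane
with plausible areas (25–1000 mm²). Each candidate's filled point set is
scored against a filled 20 mm disk centered at the candidate centroid with
the bidirectional Hausdorff distance; centering makes the score
translation-invariant. Up to two candidates scoring ≤ 5 mm are subtracted
(dilated by one voxel). The 5 mm cutoff tolerates partial-volume
raggedness on a 20 mm model while rejecting elongated fat/muscle/CSF
regions, whose scores start around 8 mm.

**Bias correction.** The simplified inhomogeneity stage models the log
field as a low-order (degree-2) 3D polynomial fit by least squares over the
dominant tissue — voxels near the median head intensity, eroded by two
voxels so one-sided partial-volume tails at tissue interfaces cannot
masquerade as a radial bias bowl. Because the tissue selection is itself
corrupted by bias, the fit iterates four times, re-selecting tissue on the
partially corrected image. A masked-Gaussian homomorphic variant
(`method="gaussian"`, scale `sigma_mm`) is retained; the polynomial is the
default because a broad Gaussian both flattens genuine linear shading
(under-correcting) and leaks anatomy at feasible scales. On a noiseless
phantom with a planted 0.8→1.2 linear field the polynomial removes ~99 %
of the within-tissue coefficient of variation while changing a bias-free
phantom by < 0.1 %. The stage is a deliberately simple surrogate with the
same interface as a full N3/N4 correction and can be disabled for
externally corrected input.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `hist.search_window_alphas` | 2 | valley search window half-width, in α |
| `hist.range_max` | 255 | internal intensity rescaling for unit bins |
| `fcm.clusters` / `fcm.mask_index` | 7 / 2 | cluster count and rough-mask index |
| `fcm.epsilon` / `fcm.fuzziness` | 0.02 / 2 | relative-SSE stop and exponent p |
| `lpf.kernel` | 3 | mean-filter size (per slice) |
| `adf.iterations` / `lambda` | 5 / 0.2 | Perona–Malik steps; λ ≤ 0.25 for stability |
| `adf.kappa` | auto | 10 % of each slice's 99th-percentile intensity |
| `bias.method` / `degree` | polynomial / 2 | log-field model |
| `eyes.offset_mm` | 15 | posterior step from the front-most line |
| `eyes.diameter_mm` | 20 | circular eye model |
| `eyes.percentile` | 60 | head-intensity percentile for candidates |
| `eyes.accept_mm` / `max_eyes` | 5 / 2 | Hausdorff acceptance and count cap |

The c = 7 / mask #2 / ε = 0.02 operating point, the 3×3 kernels, the 15 mm
offset, 20 mm model and 60th percentile are the operating point this method
family was calibrated to on clinical infant T2w data. The ADF constants, the
valley-window width, the eye acceptance cutoff and the candidate area
bounds are this package's own defaults, chosen for mild smoothing and
robust detection, and all are exposed in the config.

## The phantom

`PhantomSpec` builds a 128×128×100 voxel, 1 mm scene (a `fullsize()`
preset reproduces the 256×256×198 standard grid): nested ellipsoidal
shells — scalp/fat (160), cortical bone (12), dura/muscle (20), a thin CSF
rim (200) around brain tissue (110) — over an air background (5), with two
20 mm eyeballs (210) anterior–inferior of the brain center, Gaussian
partial-volume blur (σ 0.45 mm ≈ the point-spread of a 1 mm acquisition),
a smooth multiplicative bias field (±10 %) and additive Gaussian noise
(SD 4, brain SNR ≈ 27). Bone and dura sit near the noise floor because
they are signal voids in T2w — this is also what places the histogram
valley above them. The head nearly fills the in-plane field of view and
extends beyond the axial coverage, as in a brain-focused clinical
acquisition; consequently every slice contains brain, and the eyes poke
slightly past the anterior FOV edge. A dura/muscle shell is modeled
explicitly since separating exactly that tissue from brain is what the
fuzzy-clustering stage exists for. Ground truth: `truth_brain` is
everything inside the inner dura table (brain + interior CSF);
`truth_eyes` is the two spheres. Pathology presets add hyper-/hypo-intense
blobs or an enlarged CSF space. Generation is bitwise-deterministic per
seed.

What the phantom does *not* model: cortical folding and gyral texture,
WM/GM contrast and myelination gradients, neck/face anatomy below the
orbits, flow and motion artifacts, Rician noise statistics, and scanner
nonuniformities beyond a smooth multiplicative field. Passing the phantom
tests therefore demonstrates the pipeline's mechanics — valley
thresholding, cluster thresholds, neighbor propagation, morphology, eye
geometry — under controlled T2w-like contrast, not clinical-grade accuracy
on real data.

## Numerical choices and edge cases

- Valley ties break toward the smallest intensity; the argmax is
  restricted above the background mode (both documented above).
- FCM needs no randomness (quantile init); `init="random"` exists and uses
  a seed. Zero-distance singularities give one-hot memberships; empty
  clusters trigger one retry with c−1 and then a background-mask fallback.
- The SSE trace is non-increasing by construction (alternating exact
  minimizations); tests assert it to 1e-9 relative slack.
- Masks are resampled nearest-neighbor only; intensity volumes linearly.
  Negative input intensities are clipped to 0 with a logged count.
- An all-zero volume, an empty slice, a degenerate histogram or a failed
  per-slice FCM all degrade to empty or background masks with logged
  warnings rather than aborting the run.
- Per-slice intermediate quantities (L, th_m, FCM iterations, eye
  candidates and scores) are recorded in an `ExtractionReport` and written
  as JSON lines by the CLI's `--save-intermediates`.

## Validation results

On the default phantom (seeds 0–2) the full pipeline reaches Dice ≈ 0.975
and Precision ≈ 0.951, excludes 100 % of eye voxels and loses no brain
voxels to eye removal; two runs are bitwise identical. The residual ~2 %
Dice deficit is the +1-voxel background halo described under Refinement —
a surface effect whose relative cost is inflated by the scaled-down
phantom's surface-to-volume ratio. Stage-level oracles (an independently
written loop-based FCM, brute-force Hausdorff and Boolean-formula
evaluations, closed-form metric cases, reference morphology) are in the
test suite.

## Limitations

- Designed for infant T2-weighted contrast; the approach is not effective
  for T1-weighted or adult images, where the intensity ordering and
  bone/CSF appearance differ.
- The refinement is additive-only, so over-inclusion by the background
  mask propagates along the sweep; accuracy depends on the background
  threshold excluding the dark shells.
- Eye removal assumes roughly circular, bright, anterior eyes of ~20 mm;
  severe pathology or unusual gaze/cropping can defeat the geometric
  construction, in which case the stage disables itself and the mask is
  simply left with whatever the morphology retained.
- The bias stage is a low-order surrogate, not a replacement for N3/N4 on
  strongly shaded data.
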