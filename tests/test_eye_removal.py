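import numpy as np
import pytest
from scipy.spatial.distance import cdist

from neostrip.errors import ValidationError
from neostrip.eye_removal import (
    EyeCandidate,
    eye_candidates,
    eye_intensity_threshold,
    hausdorff_circle_score,
    locate_eye_start,
    select_and_remove_eyes,
)
from neostrip.volume_io import BinaryMask, Volume


def brute_force_hausdorff(a, b):
    """All-pairs bidirectional Hausdorff distance."""
    d = cdist(a, b)
    return max(d.min(axis=1).max(), d.min(axis=0).max())


def disk_candidate(radius_mm, center=(30.0, 30.0), shape=(64, 64)):
    idx = np.argwhere(
        (np.arange(shape[0])[:, None] - center[0]) ** 2
        + (np.arange(shape[1])[None, :] - center[1]) ** 2
        <= radius_mm ** 2
    )
    pix = idx.astype(float)
    return EyeCandidate(label=1, indices=idx, pixels_mm=pix,
                        centroid_mm=pix.mean(axis=0), anterior_fraction=1.0,
                        area_mm2=float(len(idx)))


def bar_candidate(length=30, width=4):
    idx = np.argwhere(np.ones((length, width), bool))
    pix = idx.astype(float)
    return EyeCandidate(label=1, indices=idx, pixels_mm=pix,
                        centroid_mm=pix.mean(axis=0), anterior_fraction=1.0,
                        area_mm2=float(len(idx)))


class TestIntensityThreshold:
    def test_uniform_grid_percentile(self):
        data = np.repeat(np.arange(1, 101, dtype=float), 10).reshape(10, 10, 10)
        v = Volume(data=data, affine=np.eye(4))
        T = eye_intensity_threshold(v)
        assert T == pytest.approx(60, abs=1)

    def test_single_value(self):
        data = np.zeros((6, 6, 6))
        data[2:4, 2:4, 2:4] = 42.0
        T = eye_intensity_threshold(Volume(data=data, affine=np.eye(4)))
        assert T == pytest.approx(42.0)

    def test_all_zero_rejected(self):
        with pytest.raises(ValidationError):
            eye_intensity_threshold(Volume(data=np.zeros((4, 4, 4)), affine=np.eye(4)))

    def test_phantom_threshold_between_brain_and_csf(self, default_phantom):
        vol, truth_brain, _ = default_phantom
        head = vol.data > 30
        T = eye_intensity_threshold(vol, mask=head)
        assert 110 < T < 200  # above brain-tissue mean, below CSF/eyes


class TestEyeStart:
    def test_phantom_eye_slices_located(self, default_phantom):
        from neostrip.phantom import PhantomSpec
        vol, _, truth_eyes = default_phantom
        bg = BinaryMask(data=vol.data > 30, affine=vol.affine)
        start = locate_eye_start(vol, bg)
        eye_center_z = PhantomSpec().eye_centers_mm[0][2]
        assert start is not None
        assert abs(start - eye_center_z) <= 3

    def test_eyeless_phantom_disabled(self):
        from neostrip.phantom import PhantomSpec, generate_phantom
        vol, _, _ = generate_phantom(PhantomSpec(include_eyes=False))
        bg = BinaryMask(data=vol.data > 30, affine=vol.affine)
        assert locate_eye_start(vol, bg) is None

    def test_featureless_ellipsoid_disabled(self):
        from neostrip.phantom import PhantomSpec, generate_phantom
        spec = PhantomSpec(include_eyes=False, scalp_semi=(40, 44, 56),
                           skull_semi=(40, 44, 56), dura_semi=(40, 44, 56),
                           csf_semi=(40, 44, 56), brain_semi=(39.5, 43.5, 55.5))
        vol, _, _ = generate_phantom(spec)
        bg = BinaryMask(data=vol.data > 30, affine=vol.affine)
        assert locate_eye_start(vol, bg) is None


class TestCandidates:
    def _bright_disk(self, sl, cx, cy, r, value=210.0):
        xs = np.arange(sl.shape[0])[:, None]
        ys = np.arange(sl.shape[1])[None, :]
        sl[(xs - cx) ** 2 + (ys - cy) ** 2 <= r ** 2] = value

    def test_two_anterior_disks_detected(self):
        sl = np.zeros((100, 100))
        self._bright_disk(sl, 30, 75, 10)   # anterior (y >= 50)
        self._bright_disk(sl, 70, 75, 10)   # anterior
        self._bright_disk(sl, 50, 20, 10)   # posterior blob
        cands = eye_candidates(sl, T=100.0)
        assert len(cands) == 2
        assert all(c.anterior_fraction >= 0.5 for c in cands)

    def test_empty_slice(self):
        assert eye_candidates(np.zeros((50, 50)), T=10.0) == []

    def test_straddling_disk_dropped(self):
        sl = np.zeros((100, 100))
        # 40% anterior: center posterior of the midline
        self._bright_disk(sl, 50, 47, 12)
        cands = eye_candidates(sl, T=100.0)
        assert cands == []

    def test_area_bounds(self):
        sl = np.zeros((100, 100))
        self._bright_disk(sl, 30, 80, 2)   # ~12 mm2, too small
        self._bright_disk(sl, 70, 80, 20)  # ~1256 mm2, too large
        assert eye_candidates(sl, T=100.0) == []


class TestHausdorff:
    def test_self_match_near_zero(self):
        c = disk_candidate(10.0)
        assert hausdorff_circle_score(c, diameter_mm=20.0) <= 1.0

    def test_half_size_disk_scores_radius_difference(self):
        c = disk_candidate(5.0)
        score = hausdorff_circle_score(c, diameter_mm=20.0)
        ref = brute_force_hausdorff(
            c.pixels_mm,
            disk_candidate(10.0, center=tuple(c.centroid_mm)).pixels_mm,
        )
        assert score == pytest.approx(ref, abs=1e-9)
        assert score == pytest.approx(5.0, abs=1.0)

    def test_bar_scores_high(self):
        # 30x4 bar vs centered 20 mm disk: the disk's far rim is ~8.5 mm from
        # the bar, well beyond any plausible eye acceptance cutoff
        c = bar_candidate()
        score = hausdorff_circle_score(c, diameter_mm=20.0)
        assert score >= 8.0
        ref_disk = disk_candidate(10.0, center=tuple(c.centroid_mm)).pixels_mm
        assert score == pytest.approx(brute_force_hausdorff(c.pixels_mm, ref_disk), abs=1e-9)

    def test_translation_invariance(self):
        a = disk_candidate(7.0, center=(20.0, 20.0))
        b = disk_candidate(7.0, center=(41.0, 33.0), shape=(80, 80))
        sa = hausdorff_circle_score(a)
        sb = hausdorff_circle_score(b)
        assert sa == pytest.approx(sb, abs=1.0)

    def test_symmetry_of_underlying_distance(self):
        rng = np.random.default_rng(0)
        a = rng.uniform(0, 30, (40, 2))
        b = rng.uniform(0, 30, (25, 2))
        assert brute_force_hausdorff(a, b) == pytest.approx(brute_force_hausdorff(b, a))


class TestSelectAndRemove:
    def test_no_acceptable_candidate_keeps_mask(self):
        mask = BinaryMask(data=np.ones((64, 64), bool))
        out = select_and_remove_eyes(mask, [bar_candidate()])
        np.testing.assert_array_equal(out.data, mask.data)

    def test_disks_removed_bar_kept(self):
        mask = BinaryMask(data=np.ones((64, 64), bool))
        d1 = disk_candidate(10.0, center=(20.0, 40.0))
        d2 = disk_candidate(10.0, center=(45.0, 40.0))
        bar = bar_candidate()
        out = select_and_remove_eyes(mask, [bar, d1, d2])
        assert not out.data[tuple(d1.indices.T)].any()
        assert not out.data[tuple(d2.indices.T)].any()
        # bar pixels outside the dilated disks survive
        assert out.data[25:30, 0:4].all()

    def test_purely_subtractive(self):
        rng = np.random.default_rng(1)
        mask = BinaryMask(data=rng.random((64, 64)) < 0.7)
        out = select_and_remove_eyes(mask, [disk_candidate(9.0)])
        assert not (out.data & ~mask.data).any()
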