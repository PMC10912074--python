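import math

import numpy as np
import pytest
from scipy import ndimage

from fespet import (
    DynamicImage,
    background_shell,
    compare_image_types,
    isocontour_voi,
    lesion_stats,
    screen_lesions,
    suv_image,
)
from fespet.visibility import SUVImage

from helpers import flood_fill_26


def _uniform_dynamic(sch, value):
    data = np.full((4, 4, 3, len(sch)), float(value))
    return DynamicImage(data=data, voxel_size_mm=(4.0, 4.0, 4.0), schedule=sch)


class TestSuvImage:
    def test_normalization_identity(self, sch):
        """Concentration equal to dose/weight (in cancelling units) maps to
        SUV exactly 1 everywhere."""
        dose, weight = 200.0, 70.0
        img = _uniform_dynamic(sch, dose / weight)
        suv = suv_image(img, dose, weight)
        np.testing.assert_allclose(suv.data, 1.0, rtol=1e-12)
        assert suv.window_min == (60.0, 70.0)

    def test_duration_weighted_window_mean(self, sch):
        data = np.zeros((2, 2, 1, len(sch)))
        idx = [i for i, (a, b) in enumerate(sch.frames) if a >= 60.0 and b <= 70.0]
        assert len(idx) == 2
        data[..., idx[0]] = 4.0
        data[..., idx[1]] = 6.0
        img = DynamicImage(data=data, voxel_size_mm=(4.0, 4.0, 4.0), schedule=sch)
        suv = suv_image(img, 70.0, 70.0)  # unit scaling
        np.testing.assert_allclose(suv.data, 5.0)

    def test_misaligned_window_names_offending_frames(self, sch):
        img = _uniform_dynamic(sch, 1.0)
        with pytest.raises(ValueError, match="62"):
            suv_image(img, 200.0, 70.0, window_min=(62.0, 70.0))

    def test_window_in_gap_rejected(self, sch):
        img = _uniform_dynamic(sch, 1.0)
        with pytest.raises(ValueError, match="no frames|cover"):
            suv_image(img, 200.0, 70.0, window_min=(72.0, 78.0))

    def test_invalid_dose_or_weight(self, sch):
        img = _uniform_dynamic(sch, 1.0)
        with pytest.raises(ValueError, match="positive"):
            suv_image(img, 0.0, 70.0)


class TestIsocontourVoi:
    def test_uniform_sphere_on_zero_background(self):
        img = np.zeros((20, 20, 20))
        zz = np.indices(img.shape)
        sphere = ((zz - 10.0) ** 2).sum(axis=0) <= 25.0
        img[sphere] = 3.0
        voi = isocontour_voi(img, sphere)
        np.testing.assert_array_equal(voi, sphere)

    def test_only_the_blob_holding_the_max_is_kept(self):
        img = np.zeros((16, 16, 4))
        img[2:4, 2:4, 1] = 5.0  # hotter blob
        img[10:12, 10:12, 1] = 4.0  # cooler, disjoint blob
        seed = np.zeros_like(img, dtype=bool)
        seed[1:13, 1:13, :] = True
        voi = isocontour_voi(img, seed)
        assert voi[2, 2, 1] and voi[3, 3, 1]
        assert not voi[10:12, 10:12, 1].any()

    def test_blurred_sphere_matches_bruteforce_half_max_component(self):
        """Against an explicit flood fill over the half-max threshold."""
        img = np.zeros((24, 24, 24))
        zz = np.indices(img.shape)
        sphere = ((zz - 12.0) ** 2).sum(axis=0) <= 16.0
        img[sphere] = 10.0
        img = ndimage.gaussian_filter(img, sigma=1.2)
        voi = isocontour_voi(img, sphere, margin_voxels=3)
        masked = np.where(sphere, img, -np.inf)
        peak = np.unravel_index(int(np.argmax(masked)), img.shape)
        region = np.zeros_like(sphere)
        i = np.nonzero(sphere)
        sl = tuple(slice(max(a.min() - 3, 0), a.max() + 4) for a in i)
        region[sl] = True
        thresh = region & (img >= 0.5 * img[peak])
        ref = flood_fill_26(thresh, peak)
        np.testing.assert_array_equal(voi, ref)
        # half-max volume of a blurred sphere stays near the sphere volume
        assert voi.sum() == pytest.approx(sphere.sum(), rel=0.35)

    def test_empty_seed_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            isocontour_voi(np.zeros((4, 4, 4)), np.zeros((4, 4, 4), dtype=bool))


class TestLesionStats:
    def test_hand_computed_small_arrays(self):
        img = np.array([[[4.0, 4.0, 1.0], [1.0, 3.0, 3.0]]])
        voi = np.array([[[True, True, False], [False, False, False]]])
        bg = np.array([[[False, False, True], [True, True, True]]])
        tbr, cnr = lesion_stats(img, voi, bg)
        assert tbr == pytest.approx(2.0)
        assert cnr == pytest.approx(2.0)  # (4 - 2) / population SD 1

    def test_equal_means_give_unit_tbr_zero_cnr(self):
        img = np.array([[[2.0, 2.0, 1.0, 3.0]]])
        voi = np.array([[[True, True, False, False]]])
        bg = np.array([[[False, False, True, True]]])
        tbr, cnr = lesion_stats(img, voi, bg)
        assert tbr == pytest.approx(1.0)
        assert cnr == pytest.approx(0.0)

    def test_scale_invariance(self):
        rng = np.random.default_rng(3)
        img = rng.uniform(0.5, 4.0, size=(5, 5, 4))
        voi = np.zeros_like(img, dtype=bool)
        voi[1:3, 1:3, 1] = True
        bg = np.zeros_like(voi)
        bg[3:5, 3:5, :] = True
        t1, c1 = lesion_stats(img, voi, bg)
        t2, c2 = lesion_stats(7.3 * img, voi, bg)
        assert t2 == pytest.approx(t1)
        assert c2 == pytest.approx(c1)

    def test_matches_bruteforce_loops_on_random_images(self):
        rng = np.random.default_rng(8)
        for _ in range(5):
            img = rng.uniform(0.1, 5.0, size=(8, 8, 8))
            voi = rng.random((8, 8, 8)) < 0.2
            bg = (rng.random((8, 8, 8)) < 0.3) & ~voi
            if not voi.any() or bg.sum() < 2:
                continue
            tbr, cnr = lesion_stats(img, voi, bg)
            tvals = [img[i] for i in zip(*np.nonzero(voi))]
            bvals = [img[i] for i in zip(*np.nonzero(bg))]
            tmean = sum(tvals) / len(tvals)
            bmean = sum(bvals) / len(bvals)
            bsd = math.sqrt(sum((v - bmean) ** 2 for v in bvals) / len(bvals))
            assert tbr == pytest.approx(tmean / bmean, rel=1e-12)
            assert cnr == pytest.approx((tmean - bmean) / bsd, rel=1e-12)

    def test_degenerate_backgrounds_rejected(self):
        img = np.zeros((2, 2, 2))
        voi = np.zeros_like(img, dtype=bool)
        voi[0, 0, 0] = True
        bg = np.zeros_like(voi)
        bg[1, 1, :] = True
        with pytest.raises(ValueError, match="TBR"):
            lesion_stats(img, voi, bg)  # zero background mean
        img2 = np.ones((2, 2, 2))
        with pytest.raises(ValueError, match="CNR"):
            lesion_stats(img2, voi, bg)  # zero background SD


class TestCompareImageTypes:
    def test_identical_pairs(self):
        c = compare_image_types([(2.0, 2.0), (3.0, 3.0), (5.0, 5.0)])
        assert c.ratio == pytest.approx(1.0)
        assert c.ci_low == pytest.approx(1.0) and c.ci_high == pytest.approx(1.0)
        assert c.n_higher == 0

    def test_constant_ratio_pairs(self):
        c = compare_image_types([(1.0, 2.0), (2.0, 4.0), (4.0, 8.0)])
        assert c.ratio == pytest.approx(2.0, rel=1e-12)
        assert c.ci_low == pytest.approx(2.0) and c.ci_high == pytest.approx(2.0)
        assert c.n_higher == 3

    def test_hand_computed_three_pair_oracle(self):
        """Frozen reference computed by hand from the log-paired t recipe:
        d = (ln 2, ln 3, ln 1.5)."""
        pairs = [(1.0, 2.0), (1.0, 3.0), (2.0, 3.0)]
        d = [math.log(2.0), math.log(3.0), math.log(1.5)]
        n = 3
        mean_d = sum(d) / n
        sd = math.sqrt(sum((x - mean_d) ** 2 for x in d) / (n - 1))
        se = sd / math.sqrt(n)
        t975 = 4.302652729911275  # t quantile, 2 dof
        c = compare_image_types(pairs)
        assert c.ratio == pytest.approx(math.exp(mean_d), rel=1e-12)
        assert c.ci_low == pytest.approx(math.exp(mean_d - t975 * se), rel=1e-9)
        assert c.ci_high == pytest.approx(math.exp(mean_d + t975 * se), rel=1e-9)
        assert c.n_pairs == 3 and c.n_higher == 3

    def test_input_validation(self):
        with pytest.raises(ValueError, match="at least 2"):
            compare_image_types([(1.0, 2.0)])
        with pytest.raises(ValueError, match="non-positive"):
            compare_image_types([(1.0, 2.0), (0.0, 1.0)])


class TestScreenLesions:
    def _suv(self, data):
        return SUVImage(
            data=data, voxel_size_mm=(4.0, 4.0, 4.0), injected_dose_mbq=200.0, body_weight_kg=70.0
        )

    def test_threshold_is_inclusive_at_exactly_one_point_five(self):
        data = np.zeros((4, 4, 2))
        data[0, 0, 0] = 1.49
        data[2, 2, 0] = 1.5
        m1 = np.zeros_like(data, dtype=bool)
        m1[0, 0, 0] = True
        m2 = np.zeros_like(data, dtype=bool)
        m2[2, 2, 0] = True
        recs = screen_lesions(self._suv(data), {"a": m1, "b": m2})
        by_id = {r.lesion_id: r for r in recs}
        assert not by_id["a"].included  # 1.49 < 1.5
        assert by_id["b"].included  # exactly 1.5 is in
        assert by_id["b"].suv_max == pytest.approx(1.5)

    def test_empty_candidate_list(self):
        recs = screen_lesions(self._suv(np.ones((2, 2, 2))), {})
        assert recs == []


class TestBackgroundShell:
    def test_shell_excludes_lesion_and_respects_host(self):
        lesion = np.zeros((12, 12, 12), dtype=bool)
        lesion[5:7, 5:7, 5:7] = True
        host = np.zeros_like(lesion)
        host[2:10, 2:10, 2:10] = True
        shell = background_shell(lesion, host, dilation_voxels=2)
        assert shell.any()
        assert not (shell & lesion).any()
        assert not (shell & ~host).any()
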