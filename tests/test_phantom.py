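import numpy as np
import pytest

from fespet import (
    BloodSampleTable,
    Cylinder,
    Ellipsoid,
    KineticParams,
    PhantomSpec,
    Region,
    Sphere,
    build_phantom,
    fit_metabolite_correction,
    model_tac,
    sample_blood,
    simulate_tac,
)
from fespet.phantom import BLOOD_SAMPLE_TIMES_MIN


def small_spec(**kwargs):
    """A 16x16x12 phantom with one uniform spherical region."""
    defaults = dict(
        grid_shape=(16, 16, 12),
        voxel_size_mm=(4.0, 4.0, 4.0),
        organs=[
            Region("blob", Sphere((32.0, 32.0, 24.0), 30.0), KineticParams(0.2, 0.2, 0.05, 0.0, 0.1))
        ],
        lesions=[],
        psf_fwhm_mm=0.0,
        noise_coefficient=0.0,
    )
    defaults.update(kwargs)
    return PhantomSpec(**defaults)


class TestSimulateTac:
    def test_no_uptake_equals_scaled_blood(self, inp, sch, ctx):
        kp = KineticParams(0.0, 0.0, 0.0, 0.0, 0.05)
        tac = simulate_tac(kp, inp, sch, noise_coefficient=0.0, context=ctx)
        np.testing.assert_allclose(tac.activity, 0.05 * ctx.cwb_frames, rtol=1e-12)

    def test_same_seed_reproduces_noise(self, inp, sch, ctx):
        kp = KineticParams(0.2, 0.2, 0.05, 0.0, 0.1)
        a = simulate_tac(kp, inp, sch, 0.2, seed=3, context=ctx)
        b = simulate_tac(kp, inp, sch, 0.2, seed=3, context=ctx)
        c = simulate_tac(kp, inp, sch, 0.2, seed=4, context=ctx)
        np.testing.assert_array_equal(a.activity, b.activity)
        assert not np.array_equal(a.activity, c.activity)

    def test_noise_sd_scales_with_activity_over_duration(self, inp, sch, ctx):
        """Empirical SD over 1000 replicates matches a*sqrt(mean/duration)."""
        kp = KineticParams(0.2, 0.2, 0.05, 0.0, 0.1)
        alpha = 0.3
        clean = model_tac(kp, inp, sch, context=ctx).activity
        reps = np.stack(
            [
                simulate_tac(kp, inp, sch, alpha, seed=s, context=ctx).activity
                for s in range(1000)
            ]
        )
        emp_sd = reps.std(axis=0)
        expected = alpha * np.sqrt(np.maximum(clean, 0.0) / sch.durations)
        check = expected > 1e-6
        np.testing.assert_allclose(emp_sd[check], expected[check], rtol=0.10)

    def test_frame_average_exact_for_linear_curve(self, sch):
        """A curve linear in time frame-averages exactly to its mid value."""
        from fespet import InputFunctionSet

        slope = 0.7
        lin = InputFunctionSet(
            whole_blood=lambda t: slope * np.asarray(t, dtype=float),
            p2wb_ratio=1.0,
            parent_fraction=lambda t: np.ones_like(np.asarray(t, dtype=float)),
        )
        kp = KineticParams(0.0, 0.0, 0.0, 0.0, 1.0)  # signal = Cwb
        tac = simulate_tac(kp, lin, sch, context=None)
        np.testing.assert_allclose(tac.activity, slope * sch.mid_times, rtol=1e-12, atol=1e-12)


class TestBuildPhantom:
    def test_uniform_region_voxels_match_region_tac(self, inp, sch, ctx):
        spec = small_spec()
        img, masks = build_phantom(spec, inp, sch, context=ctx)
        ref = simulate_tac(spec.organs[0].kinetics, inp, sch, context=ctx).activity
        vox = img.data[masks["blob"]]
        assert vox.shape[0] > 50
        np.testing.assert_array_equal(vox, np.tile(ref, (vox.shape[0], 1)))
        # outside the region there is no activity
        assert img.data[~masks["blob"]].max() == 0.0

    def test_psf_conserves_total_activity(self, inp, sch, ctx):
        """Gaussian blurring redistributes but does not create activity
        (away from the grid edges)."""
        spec0 = small_spec()
        spec1 = small_spec(psf_fwhm_mm=6.0)
        img0, _ = build_phantom(spec0, inp, sch, context=ctx)
        img1, _ = build_phantom(spec1, inp, sch, context=ctx)
        tot0 = img0.data.sum(axis=(0, 1, 2))
        tot1 = img1.data.sum(axis=(0, 1, 2))
        nz = tot0 > 1e-9
        np.testing.assert_allclose(tot1[nz], tot0[nz], rtol=5e-3)

    def test_lesion_voxels_excluded_from_host_mask(self, inp, sch, ctx):
        spec = small_spec(
            lesions=[
                Region("les", Sphere((32.0, 32.0, 24.0), 12.0), KineticParams(0.3, 0.2, 0.1, 0.0, 0.1))
            ]
        )
        _, masks = build_phantom(spec, inp, sch, context=ctx)
        assert masks["les"].sum() > 0
        assert not (masks["les"] & masks["blob"]).any()

    def test_voxel_noise_determinism(self, inp, sch, ctx):
        spec = small_spec(noise_coefficient=1.0, seed=9)
        img1, _ = build_phantom(spec, inp, sch, context=ctx)
        img2, _ = build_phantom(spec, inp, sch, context=ctx)
        np.testing.assert_array_equal(img1.data, img2.data)

    def test_region_outside_grid_rejected(self):
        with pytest.raises(ValueError, match="outside the grid"):
            small_spec(
                lesions=[
                    Region("bad", Sphere((62.0, 32.0, 24.0), 12.0), KineticParams(0.3, 0.2, 0.1))
                ]
            )

    def test_region_requires_kinetics_or_tac(self):
        with pytest.raises(ValueError, match="exactly one"):
            Region("r", Sphere((10.0, 10.0, 10.0), 4.0))

    def test_literal_tac_region(self, inp, sch, ctx):
        vals = np.linspace(0.0, 5.0, len(sch))
        spec = small_spec(
            organs=[Region("flat", Ellipsoid((32.0, 32.0, 24.0), (20.0, 20.0, 16.0)), None, vals)]
        )
        img, masks = build_phantom(spec, inp, sch, context=ctx)
        np.testing.assert_array_equal(img.data[masks["flat"]][0], vals)


class TestDefaultPhantom:
    def test_masks_partition_and_aorta_is_blood(self, noiseless_phantom, ctx):
        spec, img, masks = noiseless_phantom
        total = np.zeros(img.data.shape[:3], dtype=int)
        for m in masks.values():
            total += m
        assert total.max() == 1  # ownership is exclusive
        np.testing.assert_allclose(
            img.data[masks["aorta"]][0], ctx.cwb_frames, rtol=1e-12
        )

    def test_lesion_suv_range_spans_configured_defaults(self, noiseless_phantom, sch):
        """Generator round trip: lesion SUVmeans cover a clinical range with
        the median near 3.8 g/mL."""
        spec, img, masks = noiseless_phantom
        w = [i for i, (a, b) in enumerate(sch.frames) if a >= 60.0 and b <= 70.0]
        suvs = sorted(
            img.data[m][:, w].mean() * spec.body_weight_kg / spec.injected_dose_mbq
            for n, m in masks.items()
            if n.startswith("lesion")
        )
        assert len(suvs) == 8
        assert 1.0 < suvs[0] < 2.5 and 5.5 < suvs[-1] < 9.0
        assert np.median(suvs) == pytest.approx(3.77, abs=0.5)


class TestSampleBlood:
    def test_noiseless_ratio_and_parent_fraction_exact(self, inp):
        tab = sample_blood(inp, noise_cv=0.0)
        np.testing.assert_allclose(tab.plasma / tab.whole_blood, inp.p2wb_ratio)
        np.testing.assert_allclose(tab.parent_fraction, np.asarray(inp.parent_fraction(tab.time_min)))

    def test_default_sampling_times(self, inp):
        tab = sample_blood(inp)
        assert len(tab) == 7
        np.testing.assert_array_equal(tab.time_min, BLOOD_SAMPLE_TIMES_MIN)

    def test_grand_mean_ratio_approaches_configured_value(self, inp):
        """Across 8 subjects at 3% noise the mean estimated ratio is close
        to the generator's 1.50."""
        ratios = [
            fit_metabolite_correction(sample_blood(inp, noise_cv=0.03, seed=100 + s)).p2wb_ratio
            for s in range(8)
        ]
        assert np.mean(ratios) == pytest.approx(1.50, abs=0.05)

    def test_nonpositive_times_rejected(self, inp):
        with pytest.raises(ValueError, match="positive"):
            sample_blood(inp, times=(0.0, 2.0, 5.0))

    def test_table_validation(self):
        with pytest.raises(ValueError, match="increasing"):
            BloodSampleTable([2.0, 2.0], [1.0, 1.0], [1.5, 1.5], [0.9, 0.8])
        with pytest.raises(ValueError, match="\\[0, 1\\]"):
            BloodSampleTable([2.0, 5.0], [1.0, 1.0], [1.5, 1.5], [0.9, 1.2])


class TestPrimitives:
    def test_cylinder_contains(self):
        cyl = Cylinder((10.0, 10.0), 5.0, (0.0, 20.0))
        pts = np.array([[10.0, 10.0, 10.0], [16.0, 10.0, 10.0], [10.0, 10.0, 25.0]])
        np.testing.assert_array_equal(cyl.contains(pts), [True, False, False])

    def test_invalid_primitives(self):
        with pytest.raises(ValueError):
            Sphere((0.0, 0.0, 0.0), 0.0)
        with pytest.raises(ValueError):
            Ellipsoid((0.0, 0.0, 0.0), (1.0, -1.0, 1.0))
        with pytest.raises(ValueError):
            Cylinder((0.0, 0.0), 1.0, (5.0, 2.0))
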