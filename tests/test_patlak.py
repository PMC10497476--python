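import numpy as np
import pytest

import oracles
from petkinetics.core import (
    DynamicImage,
    InputFunction,
    TimeActivityCurve,
    make_schedule,
    preset_protocol,
)
from petkinetics.patlak import (
    patlak_fit,
    patlak_transform,
    patlak_voxelwise,
    roi_patlak,
)
from petkinetics.phantom import (
    KineticParams,
    frame_average,
    tissue_curve_2ti,
)


def make_if(schedule, values):
    return InputFunction(TimeActivityCurve(schedule, np.asarray(values), "C_P"))


class TestPatlakTransform:
    def test_constant_curves_give_normalized_time_axis(self):
        sch = make_schedule([(20, 180)])
        cp = make_if(sch, np.full(20, 5.0))
        ct = TimeActivityCurve(sch, np.full(20, 2.0))
        # holding Cp constant back to t = 0 (prepend suppressed): x = t
        x, y = patlak_transform(ct, cp, t_star=10.0, prepend_zero=False)
        mids = sch.mid_times_min
        assert x == pytest.approx(mids[mids >= 10.0])
        assert y == pytest.approx(np.full(x.size, 0.4))

    def test_linear_construction_is_exact(self):
        sch = preset_protocol("P-29f")
        cp_vals = np.exp(-0.05 * sch.mid_times_min) * 20.0
        a, b = 0.02, 0.5
        # rebuild the integral with the same (0,0)-anchored trapezoid
        t = np.concatenate([[0.0], sch.mid_times_min])
        v = np.concatenate([[0.0], cp_vals])
        integral = np.cumsum(np.diff(t) * (v[1:] + v[:-1]) / 2.0)
        ct_vals = a * integral + b * cp_vals
        x, y = patlak_transform(
            TimeActivityCurve(sch, ct_vals), make_if(sch, cp_vals), 10.0
        )
        assert y == pytest.approx(a * x + b, rel=1e-12)

    def test_matches_stepwise_recomputation_on_lesion_curve(self, fine_bolus):
        t, cp_fine = fine_bolus
        sch = preset_protocol("P-100f")
        params = KineticParams(K1=0.1, k2=0.1, k3=0.05, Vb=0.0)
        ct_fine = tissue_curve_2ti(params, cp_fine, t)
        ct_vals = frame_average(ct_fine, sch, t=t)
        cp_vals = frame_average(cp_fine, sch, t=t)
        x, y = patlak_transform(
            TimeActivityCurve(sch, ct_vals), make_if(sch, cp_vals), 10.0
        )
        ox, oy = oracles.patlak_points(sch.mid_times_min, ct_vals, cp_vals, 10.0)
        assert x == pytest.approx(ox, rel=1e-12)
        assert y == pytest.approx(oy, rel=1e-12)

    def test_nonpositive_plasma_frames_dropped_with_warning(self):
        sch = make_schedule([(20, 180)])
        cp_vals = np.full(20, 5.0)
        cp_vals[12] = 0.0
        ct = TimeActivityCurve(sch, np.ones(20))
        with pytest.warns(UserWarning, match="non-positive plasma"):
            x, _ = patlak_transform(ct, make_if(sch, cp_vals), 10.0)
        mids = sch.mid_times_min
        assert x.size == int((mids >= 10).sum()) - 1

    def test_too_few_usable_frames_rejected(self):
        sch = make_schedule([(4, 900)])
        ct = TimeActivityCurve(sch, np.ones(4))
        with pytest.raises(ValueError, match="fewer than 2"):
            patlak_transform(ct, make_if(sch, np.ones(4)), t_star=50.0)

    def test_cp_on_other_schedule_is_resampled(self):
        sch = preset_protocol("P-29f")
        dense = preset_protocol("P-100f")
        cp_dense = make_if(dense, 10.0 + dense.mid_times_min)
        ct = TimeActivityCurve(sch, np.ones(29))
        x, y = patlak_transform(ct, cp_dense, 10.0)
        assert np.all(np.isfinite(x)) and x.size == y.size


class TestPatlakFit:
    def test_exact_line(self):
        x = np.linspace(10, 50, 12)
        ki, intercept, sse = patlak_fit(x, 0.02 * x + 0.5)
        assert ki == pytest.approx(0.02, rel=1e-12)
        assert intercept == pytest.approx(0.5, rel=1e-12)
        assert sse == pytest.approx(0.0, abs=1e-20)

    def test_two_points_fit_perfectly(self):
        ki, intercept, sse = patlak_fit([1.0, 3.0], [5.0, 1.0])
        assert (ki, intercept) == pytest.approx((-2.0, 7.0))
        assert sse == pytest.approx(0.0, abs=1e-24)

    def test_matches_normal_equation_oracle(self):
        rng = np.random.default_rng(2)
        x = np.sort(rng.uniform(5, 60, 10))
        y = 0.015 * x + 0.4 + rng.normal(0, 0.05, 10)
        mine = patlak_fit(x, y)
        theirs = oracles.ols_fit(x, y)
        for a, b in zip(mine, theirs):
            assert a == pytest.approx(b, rel=1e-10, abs=1e-14)

    def test_degenerate_x_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            patlak_fit([2.0, 2.0, 2.0], [1.0, 2.0, 3.0])


class TestPatlakVoxelwise:
    def test_uniform_image_equals_roi_fit(self):
        sch = preset_protocol("P-19f")
        cp = make_if(sch, 10.0 * np.exp(-0.02 * sch.mid_times_min) + 5.0)
        t = np.concatenate([[0.0], sch.mid_times_min])
        v = np.concatenate([[0.0], cp.values])
        integral = np.cumsum(np.diff(t) * (v[1:] + v[:-1]) / 2.0)
        ct_vals = 0.01 * integral + 0.3 * cp.values
        data = np.broadcast_to(ct_vals, (4, 4, 4, 19)).copy()
        dyn = DynamicImage(data, sch)
        res = patlak_voxelwise(dyn, cp, 10.0)
        labels = np.ones((4, 4, 4), dtype=np.int16)
        roi = roi_patlak(dyn, cp, 10.0, labels, 1)
        assert res.ki == pytest.approx(np.full((4, 4, 4), roi.ki), rel=1e-9)
        assert res.intercept == pytest.approx(
            np.full((4, 4, 4), roi.intercept), rel=1e-9
        )

    def test_every_voxel_matches_per_voxel_ols_oracle(self, small_noisy_phantom):
        spec, dyn, _, true_if = small_noisy_phantom
        res = patlak_voxelwise(dyn, true_if, 10.0)
        mids = dyn.schedule.mid_times_min
        rng = np.random.default_rng(0)
        flat = [tuple(v) for v in rng.integers(0, dyn.shape3d, size=(50, 3))]
        for idx in flat:
            ct = dyn.data[idx].astype(float)
            x, y = oracles.patlak_points(mids, ct, true_if.values, 10.0)
            ki, intercept, sse = oracles.ols_fit(x, y)
            assert res.ki[idx] == pytest.approx(ki, rel=1e-9, abs=1e-15)
            assert res.intercept[idx] == pytest.approx(intercept, rel=1e-9, abs=1e-15)
            assert res.sse[idx] == pytest.approx(sse, rel=1e-7, abs=1e-15)

    def test_masked_voxels_take_fill_value(self, small_noisy_phantom):
        spec, dyn, _, true_if = small_noisy_phantom
        mask = spec.labels == 2
        res = patlak_voxelwise(dyn, true_if, 10.0, mask=mask, fill_value=-1.0)
        assert np.all(res.ki[~mask] == -1.0)
        full = patlak_voxelwise(dyn, true_if, 10.0)
        assert res.ki[mask] == pytest.approx(full.ki[mask], rel=1e-12)

    def test_scaling_tissue_scales_slope_and_intercept(self, small_noisy_phantom):
        spec, dyn, _, true_if = small_noisy_phantom
        base = patlak_voxelwise(dyn, true_if, 10.0)
        scaled = patlak_voxelwise(
            DynamicImage(dyn.data * 3.0, dyn.schedule, affine=dyn.affine),
            true_if,
            10.0,
        )
        assert scaled.ki == pytest.approx(3.0 * base.ki, rel=1e-4, abs=1e-8)
        assert scaled.intercept == pytest.approx(3.0 * base.intercept, rel=1e-4, abs=1e-8)

    def test_clip_negative_ki_flag(self, small_noisy_phantom):
        spec, dyn, _, true_if = small_noisy_phantom
        res = patlak_voxelwise(dyn, true_if, 10.0, clip_negative_ki=True)
        assert res.ki.min() >= 0.0


class TestRoiPatlak:
    def test_single_voxel_roi_equals_voxelwise(self, small_noisy_phantom):
        spec, dyn, _, true_if = small_noisy_phantom
        labels = np.zeros(dyn.shape3d, dtype=np.int16)
        labels[3, 3, 3] = 9
        roi = roi_patlak(dyn, true_if, 10.0, labels, 9)
        vox = patlak_voxelwise(dyn, true_if, 10.0)
        assert roi.ki == pytest.approx(vox.ki[3, 3, 3], rel=1e-9)
        assert roi.intercept == pytest.approx(vox.intercept[3, 3, 3], rel=1e-9)

    def test_uniform_region_equals_voxelwise_value(self, small_noiseless_phantom):
        spec, dyn, _, true_if = small_noiseless_phantom
        roi = roi_patlak(dyn, true_if, 10.0, spec.labels, 3)
        vox = patlak_voxelwise(dyn, true_if, 10.0)
        region = vox.ki[spec.labels == 3]
        assert roi.ki == pytest.approx(region.mean(), rel=1e-5)

    def test_empty_label_rejected(self, small_noiseless_phantom):
        spec, dyn, _, true_if = small_noiseless_phantom
        with pytest.raises(ValueError, match="no voxels"):
            roi_patlak(dyn, true_if, 10.0, spec.labels, 99)

    @pytest.mark.parametrize("t_star", [10.0, 30.0])
    def test_exact_regime_recovers_table_ki(self, fine_bolus, t_star):
        """Pure trapping at the lesion rate: Ki = 23.5 uL/min/cm^3."""
        t, cp_fine = fine_bolus
        sch = preset_protocol("P-100f")
        params = KineticParams(K1=0.0235, k2=0.0, k3=0.0, Vb=0.0)
        ct_fine = tissue_curve_2ti(params, cp_fine, t)
        ct = TimeActivityCurve(sch, frame_average(ct_fine, sch, t=t))
        cp = make_if(sch, frame_average(cp_fine, sch, t=t))
        x, y = patlak_transform(ct, cp, t_star)
        ki, _, _ = patlak_fit(x, y)
        assert ki * 1000.0 == pytest.approx(23.5, rel=5e-3)
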