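"""Frame arithmetic, integration, decay correction and ROI extraction."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import petkin as pk
from petkin.tac_core import long_schedule


class TestFrameSchedule:
    def test_packaged_schedule_shape(self, schedule):
        assert len(schedule) == 30
        assert schedule.total_duration_s == 3600.0
        assert np.allclose(schedule.durations_s[:12], 10.0)
        assert np.allclose(schedule.durations_s[-2:], 600.0)
        # contiguous frames
        assert np.allclose(schedule.ends[:-1], schedule.starts[1:])

    def test_midpoints(self, schedule):
        mids = pk.frame_midpoints(schedule)
        assert mids.shape == (30,)
        assert mids[0] == pytest.approx(5.0 / 60.0)
        assert mids[-1] == pytest.approx(55.0)  # the 3000-3600 s frame

    def test_single_frame_midpoint(self):
        sched = pk.FrameSchedule(starts=[0.0], ends=[60.0])
        assert pk.frame_midpoints(sched)[0] == pytest.approx(0.5)

    def test_long_schedule_extends_to_90min(self):
        sched = long_schedule()
        assert sched.total_duration_s == 5400.0
        assert sched.midpoints_min[-1] == pytest.approx(85.0)

    @pytest.mark.parametrize(
        "starts,ends",
        [([], []), ([0, 0], [10, 20]), ([0, 10], [10, 5]), ([10, 0], [20, 10])],
    )
    def test_invalid_schedules_rejected(self, starts, ends):
        with pytest.raises(ValueError):
            pk.FrameSchedule(starts=starts, ends=ends)


class TestCumulativeIntegral:
    def test_constant_concentration(self):
        ends = np.arange(1, 61) * 60.0
        sched = pk.FrameSchedule(starts=ends - 60.0, ends=ends)
        tac = pk.TimeActivityCurve(schedule=sched, values=np.ones(60))
        integral = pk.cumulative_integral(tac)
        # ∫ of C=1 up to the last midpoint (59.5 min)
        assert integral[-1] == pytest.approx(59.5, rel=1e-2)

    def test_zero_everywhere(self, schedule):
        tac = pk.TimeActivityCurve(schedule=schedule, values=np.zeros(30))
        assert np.all(pk.cumulative_integral(tac) == 0.0)

    def test_linear_ramp_matches_closed_form(self):
        ends = np.arange(1, 61) * 60.0
        sched = pk.FrameSchedule(starts=ends - 60.0, ends=ends)
        t = sched.midpoints_min
        tac = pk.TimeActivityCurve(schedule=sched, values=t)
        integral = pk.cumulative_integral(tac)
        # trapezoid is exact for a linear integrand except the first cell
        assert np.allclose(integral[1:], t[1:] ** 2 / 2.0, rtol=1e-2)

    def test_linearity(self, schedule):
        rng = np.random.default_rng(7)
        c1 = rng.uniform(0, 10, 30)
        c2 = rng.uniform(0, 10, 30)
        mk = lambda v: pk.TimeActivityCurve(schedule=schedule, values=v)
        lhs = pk.cumulative_integral(mk(3.0 * c1 + 2.0 * c2))
        rhs = 3.0 * pk.cumulative_integral(mk(c1)) + 2.0 * pk.cumulative_integral(mk(c2))
        assert np.allclose(lhs, rhs, rtol=0, atol=1e-12)

    def test_nondecreasing_for_nonnegative_values(self, schedule):
        rng = np.random.default_rng(3)
        tac = pk.TimeActivityCurve(schedule=schedule, values=rng.uniform(0, 5, 30))
        assert np.all(np.diff(pk.cumulative_integral(tac)) >= 0)


class TestDecayCorrect:
    def test_one_half_life_doubles(self):
        sched = pk.FrameSchedule(starts=[67.71 * 60 - 30], ends=[67.71 * 60 + 30])
        tac = pk.TimeActivityCurve(schedule=sched, values=[1.0],
                                   decay_corrected=False)
        out = pk.decay_correct(tac, direction="to_injection")
        assert out.values[0] == pytest.approx(2.0)
        assert out.decay_corrected

    def test_two_half_lives(self):
        t_mid_s = 2 * 67.71 * 60
        sched = pk.FrameSchedule(starts=[t_mid_s - 30], ends=[t_mid_s + 30])
        tac = pk.TimeActivityCurve(schedule=sched, values=[4.0])
        assert pk.decay_correct(tac).values[0] == pytest.approx(16.0)

    @settings(deadline=None, max_examples=25)
    @given(st.lists(st.floats(0.0, 100.0), min_size=30, max_size=30))
    def test_roundtrip_identity(self, values):
        sched = pk.default_schedule()
        tac = pk.TimeActivityCurve(schedule=sched, values=values)
        back = pk.decay_correct(pk.decay_correct(tac, direction="to_injection"),
                                direction="undo")
        assert np.allclose(back.values, tac.values, rtol=1e-12, atol=1e-12)

    def test_negative_half_life_rejected(self, schedule):
        tac = pk.TimeActivityCurve(schedule=schedule, values=np.ones(30))
        with pytest.raises(ValueError):
            pk.decay_correct(tac, half_life_min=-1.0)


class TestExtractRoiTac:
    def _phantom(self, value=5.0, n_frames=4):
        vox = np.zeros((4, 4, 4, n_frames))
        labels = np.zeros((4, 4, 4), dtype=int)
        labels[1:3, 1:3, 1:3] = 1
        vox[labels == 1] = value
        return pk.LabeledImage4D(voxels=vox, voxel_volume_ml=0.5, labels=labels)

    def _schedule(self, n):
        ends = np.arange(1, n + 1) * 60.0
        return pk.FrameSchedule(starts=ends - 60.0, ends=ends)

    def test_uniform_phantom(self):
        img = self._phantom(value=5.0)
        tac = pk.extract_roi_tac(img, self._schedule(4), 1)
        assert np.allclose(tac.values, 5.0)
        assert tac.volume_ml == pytest.approx(8 * 0.5)

    def test_two_voxel_mean(self):
        vox = np.zeros((2, 1, 1, 1))
        vox[0, 0, 0, 0], vox[1, 0, 0, 0] = 2.0, 4.0
        labels = np.ones((2, 1, 1), dtype=int)
        img = pk.LabeledImage4D(voxels=vox, voxel_volume_ml=1.0, labels=labels)
        tac = pk.extract_roi_tac(img, self._schedule(1), 1)
        assert tac.values[0] == pytest.approx(3.0)

    def test_voxel_order_invariance_and_volume_additivity(self):
        rng = np.random.default_rng(11)
        vox = rng.uniform(0, 10, (4, 4, 4, 3))
        labels = rng.integers(1, 3, (4, 4, 4))
        sched = self._schedule(3)
        img = pk.LabeledImage4D(voxels=vox, voxel_volume_ml=0.25, labels=labels)
        perm = rng.permutation(4)
        img_p = pk.LabeledImage4D(voxels=vox[perm], voxel_volume_ml=0.25,
                                  labels=labels[perm])
        t1 = pk.extract_roi_tac(img, sched, 1)
        t1p = pk.extract_roi_tac(img_p, sched, 1)
        assert np.allclose(t1.values, t1p.values)
        t2 = pk.extract_roi_tac(img, sched, 2)
        assert t1.volume_ml + t2.volume_ml == pytest.approx(64 * 0.25)

    def test_missing_label_raises(self):
        img = self._phantom()
        with pytest.raises(KeyError):
            pk.extract_roi_tac(img, self._schedule(4), 99)

    def test_frame_mismatch_raises(self):
        img = self._phantom(n_frames=4)
        with pytest.raises(ValueError):
            pk.extract_roi_tac(img, self._schedule(5), 1)


class TestIO:
    def test_nifti_roundtrip_with_label_map(self, tmp_path, config):
        img, truth = __import__("petkin").synth_phantom(config, seed=1, grid=8)
        paths = (tmp_path / "dyn.nii.gz", tmp_path / "mask.nii.gz",
                 tmp_path / "labels.yaml")
        pk.write_labeled_image_nifti(img, *paths)
        back = pk.read_labeled_image_nifti(*paths)
        assert np.allclose(back.voxels, img.voxels, atol=1e-4)
        assert np.array_equal(back.labels, img.labels)
        assert back.voxel_volume_ml == pytest.approx(img.voxel_volume_ml,
                                                     rel=1e-4)
        assert back.label_names == img.label_names
        code = next(iter(img.label_names))
        tac = pk.extract_roi_tac(back, config.schedule, code)
        assert tac.region_label == img.label_names[code]


    def test_tac_csv_roundtrip(self, tmp_path, schedule):
        rng = np.random.default_rng(5)
        tacs = {
            "pancreas": pk.TimeActivityCurve(
                schedule=schedule, values=rng.uniform(0, 10, 30),
                region_label="pancreas"),
            "aorta": pk.TimeActivityCurve(
                schedule=schedule, values=rng.uniform(0, 30, 30),
                region_label="aorta"),
        }
        path = tmp_path / "tacs.csv"
        pk.write_tac_csv(path, tacs)
        back = pk.read_tac_csv(path)
        assert set(back) == {"pancreas", "aorta"}
        assert np.allclose(back["pancreas"].values, tacs["pancreas"].values)
        assert np.allclose(back["aorta"].schedule.ends, schedule.ends)
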