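"""Geometric normalization, resampling, cropping, flattening, leg speed."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from gaitformer.skeleton_core import (COCO18, EPS_GUARD, N_JOINTS, PoseFrame,
                                      RawTracklet, center_crop, flatten,
                                      mean_leg_speed, normalize_frame,
                                      normalize_sequence,
                                      resample_to_reference_fps, unflatten)
from .conftest import random_pose_frame


def pelvis_of(frame):
    return 0.5 * (frame.coords[8] + frame.coords[11])


class TestJointLayout:
    def test_coco18_is_consistent(self):
        assert len(COCO18.names) == 18
        assert set(COCO18.feet_indices) <= set(COCO18.leg_indices)
        for left, right in COCO18.left_right_pairs:
            assert COCO18.names[left][0] == "L"
            assert COCO18.names[right][0] == "R"
            assert COCO18.names[left][1:] == COCO18.names[right][1:]

    def test_rejects_wrong_joint_count(self):
        from gaitformer.skeleton_core import JointLayout

        with pytest.raises(ValueError):
            JointLayout(names=("A",) * 17, left_right_pairs=(),
                        feet_indices=(), leg_indices=())


class TestNormalizeFrame:
    def test_worked_example(self):
        """Pelvis (10,20), shoulders at x=9/11, neck at y=18: joint (11,18)
        lands at (0.5, -1.0)."""
        coords = np.zeros((N_JOINTS, 2))
        coords[8] = coords[11] = (10.0, 20.0)       # hips -> pelvis (10, 20)
        coords[2, 0], coords[5, 0] = 9.0, 11.0      # shoulder span 2
        coords[1] = (10.0, 18.0)                    # neck -> torso height 2
        coords[0] = (11.0, 18.0)                    # probe joint
        out = normalize_frame(PoseFrame(coords, np.full(N_JOINTS, 0.9)))
        np.testing.assert_allclose(out.coords[0], (0.5, -1.0))

    def test_pelvis_maps_to_origin_and_unit_spans(self, rng):
        for _ in range(50):
            out = normalize_frame(random_pose_frame(rng))
            np.testing.assert_allclose(pelvis_of(out), 0.0, atol=1e-12)
            assert abs(abs(out.coords[2, 0] - out.coords[5, 0]) - 1.0) < 1e-12
            assert abs(abs(out.coords[1, 1] - pelvis_of(out)[1]) - 1.0) < 1e-12

    def test_idempotent(self, rng):
        frame = random_pose_frame(rng)
        once = normalize_frame(frame)
        twice = normalize_frame(once)
        np.testing.assert_allclose(twice.coords, once.coords, atol=1e-12)

    @given(ax=st.floats(-1e4, 1e4), ay=st.floats(-1e4, 1e4))
    @settings(max_examples=30, deadline=None)
    def test_translation_invariance(self, ax, ay):
        rng = np.random.default_rng(0)
        frame = random_pose_frame(rng)
        shifted = PoseFrame(frame.coords + np.array([ax, ay]), frame.conf)
        np.testing.assert_allclose(normalize_frame(shifted).coords,
                                   normalize_frame(frame).coords, atol=1e-8)

    @given(s=st.floats(1e-3, 1e3))
    @settings(max_examples=30, deadline=None)
    def test_scale_invariance(self, s):
        rng = np.random.default_rng(1)
        frame = random_pose_frame(rng)
        scaled = PoseFrame(frame.coords * s, frame.conf)
        np.testing.assert_allclose(normalize_frame(scaled).coords,
                                   normalize_frame(frame).coords, atol=1e-9)

    def test_confidences_preserved_bit_exact(self, rng):
        frame = random_pose_frame(rng)
        out = normalize_frame(frame)
        assert np.array_equal(out.conf, frame.conf)

    def test_degenerate_frame_flagged_not_crashed(self):
        coords = np.ones((N_JOINTS, 2))   # all joints coincide
        out = normalize_frame(PoseFrame(coords, np.full(N_JOINTS, 0.5)))
        assert out.degenerate
        assert np.all(np.isfinite(out.coords))


class TestNormalizeSequence:
    def test_maps_each_frame(self, walking_tracklet):
        seq = normalize_sequence(walking_tracklet)
        assert len(seq) == len(walking_tracklet)
        spans = np.abs(seq.data[:, 2, 0] - seq.data[:, 5, 0])
        np.testing.assert_allclose(spans, 1.0, atol=1e-9)
        pelvis = 0.5 * (seq.data[:, 8, :2] + seq.data[:, 11, :2])
        np.testing.assert_allclose(pelvis, 0.0, atol=1e-9)

    def test_empty_tracklet_rejected(self):
        with pytest.raises(ValueError):
            normalize_sequence(RawTracklet(frames=[], fps=24.0))


class TestResample:
    def test_halving_frame_rate(self, rng):
        coords = rng.normal(size=(100, N_JOINTS, 2))
        track = RawTracklet.from_arrays(coords, np.full((100, N_JOINTS), 0.9), fps=48.0)
        out = resample_to_reference_fps(track, 24.0)
        assert len(out) == 50
        assert out.fps == 24.0
        # same wall-clock span
        assert (len(out) - 1) / out.fps == pytest.approx((100 - 1) / 48.0, abs=1 / 24.0)

    def test_identity_at_reference_fps(self, walking_tracklet):
        out = resample_to_reference_fps(walking_tracklet, walking_tracklet.fps)
        assert len(out) == len(walking_tracklet)
        np.testing.assert_allclose(out.coords, walking_tracklet.coords, atol=1e-12)
        np.testing.assert_allclose(out.confs, walking_tracklet.confs, atol=1e-12)

    def test_linear_motion_round_trip(self):
        t = np.arange(96)[:, None, None]
        coords = np.tile(t * np.array([0.5, -0.25]), (1, N_JOINTS, 1))
        track = RawTracklet.from_arrays(coords, np.full((96, N_JOINTS), 0.8), fps=24.0)
        down = resample_to_reference_fps(track, 12.0)
        back = resample_to_reference_fps(down, 24.0)
        np.testing.assert_allclose(back.coords, coords[:len(back)], atol=1e-9)

    def test_single_frame_rejected(self, rng):
        track = RawTracklet.from_arrays(rng.normal(size=(1, N_JOINTS, 2)),
                                        np.full((1, N_JOINTS), 0.9), fps=24.0)
        with pytest.raises(ValueError):
            resample_to_reference_fps(track)


class TestCenterCrop:
    @pytest.mark.parametrize("L,T,start", [(48, 48, 0), (100, 48, 26), (49, 48, 0)])
    def test_window_placement(self, L, T, start, rng):
        seq = unflatten(rng.normal(size=(L, 54)))
        out = center_crop(seq, T)
        assert len(out) == T
        np.testing.assert_array_equal(out.data, seq.data[start:start + T])

    def test_too_short_rejected(self, rng):
        with pytest.raises(ValueError):
            center_crop(unflatten(rng.normal(size=(47, 54))), 48)


class TestFlatten:
    def test_row_layout_and_round_trip(self, normalized_walker):
        mat = flatten(normalized_walker)
        assert mat.shape == (len(normalized_walker), 54)
        np.testing.assert_array_equal(mat[0].reshape(18, 3),
                                      normalized_walker.data[0])
        back = unflatten(mat, ref_fps=normalized_walker.ref_fps)
        np.testing.assert_array_equal(back.data, normalized_walker.data)

    def test_zero_frame_flattens_to_zero_row(self):
        seq = unflatten(np.zeros((3, 54)))
        assert not flatten(seq).any()


class TestMeanLegSpeed:
    def test_static_sequence_is_zero(self):
        seq = unflatten(np.tile(np.arange(54, dtype=float), (10, 1)))
        assert mean_leg_speed(seq) == 0.0

    def test_constant_displacement(self):
        """Every leg joint moving exactly (0.003, 0) per frame gives 0.003."""
        data = np.zeros((20, 18, 3))
        for t in range(20):
            data[t, list(COCO18.leg_indices), 0] = 0.003 * t
        assert mean_leg_speed(unflatten(data.reshape(20, 54))) == pytest.approx(0.003)

    def test_walker_in_keep_band(self, normalized_walker):
        assert 0.0015 <= mean_leg_speed(normalized_walker) <= 0.09

    def test_needs_two_frames(self):
        with pytest.raises(ValueError):
            mean_leg_speed(unflatten(np.zeros((1, 54))))
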