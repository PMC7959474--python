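"""Joint angles, segment lengths and range of motion."""

import math

import numpy as np
import pytest

from handkin import (AngleTrajectory, Recording, SensorModel, TaskProfile,
                     TruthTrajectories, angle_trajectories, forward_pose,
                     joint_angle, render_stream, rom, rom_difference,
                     segment_lengths)
from handkin import hand
from handkin.exceptions import (DegenerateGeometryError, InsufficientDataError,
                                ValidationError)


def oracle_angle(a, b, c):
    """Independently coded dot-product/arccos bend angle (degrees)."""
    u = [b[i] - a[i] for i in range(3)]
    v = [c[i] - b[i] for i in range(3)]
    dot = sum(ui * vi for ui, vi in zip(u, v))
    nu = math.sqrt(sum(ui * ui for ui in u))
    nv = math.sqrt(sum(vi * vi for vi in v))
    return math.degrees(math.acos(max(-1.0, min(1.0, dot / (nu * nv)))))


def pose_recording(geometry, angles, n_frames=3):
    arrays = {k: np.full(n_frames, angles.get(k, 0.0)) for k in hand.ANGLE_KEYS}
    pos = hand.pose_trajectory(geometry, arrays)
    return Recording(np.arange(n_frames) / 150.0, hand.LANDMARKS, pos,
                     nominal_rate=150.0)


class TestJointAngle:
    def test_collinear_points_give_zero(self):
        assert joint_angle((0, 0, 0), (0, 0, 1), (0, 0, 2)) == pytest.approx(0.0, abs=1e-9)

    def test_orthogonal_segments_give_ninety(self):
        assert joint_angle((0, 0, 0), (0, 0, 1), (1, 0, 1)) == pytest.approx(90.0, abs=1e-12)

    def test_matches_independent_oracle_on_random_triples(self):
        rng = np.random.default_rng(1234)
        worst = 0.0
        for _ in range(1000):
            a, b, c = rng.uniform(-100, 100, size=(3, 3))
            worst = max(worst, abs(joint_angle(a, b, c) - oracle_angle(a, b, c)))
        assert worst < 1e-9

    def test_invariant_to_rotation_translation_scaling(self):
        from scipy.spatial.transform import Rotation

        rng = np.random.default_rng(5)
        a, b, c = rng.uniform(-10, 10, size=(3, 3))
        ref = joint_angle(a, b, c)
        rot = Rotation.from_euler("zyx", [40, 10, -70], degrees=True)
        shift = np.array([3.0, -8.0, 1.0])
        # uniform scale then rotate+shift: a similarity transform
        assert joint_angle(*[rot.apply(p * 2.5) + shift for p in (a, b, c)]) \
            == pytest.approx(ref, abs=1e-9)

    def test_zero_length_segment_raises(self):
        with pytest.raises(DegenerateGeometryError):
            joint_angle((1, 2, 3), (1, 2, 3), (4, 5, 6))


class TestAngleTrajectories:
    def test_straight_hand_all_zero(self, geometry):
        rec = pose_recording(geometry, {})
        trajs = angle_trajectories(rec)
        for traj in trajs.values():
            # arccos near 0 deg resolves angles only to ~sqrt(machine eps)
            assert np.max(np.abs(traj.angles)) < 1e-5
        for joint in ("middle_mcp", "middle_pip", "middle_dip"):
            # the middle finger lies exactly along +Z: bitwise collinear
            assert np.max(np.abs(trajs[joint].angles)) < 1e-9

    def test_constant_pip_flexion_round_trip(self, geometry):
        rec = pose_recording(geometry, {"index_pip": 30.0})
        trajs = angle_trajectories(rec)
        assert np.allclose(trajs["index_pip"].angles, 30.0, atol=1e-9)

    def test_noiseless_flexion_bundle_matches_truth(self, geometry):
        truth = TruthTrajectories(TaskProfile.finger_flexion("middle"))
        rec = render_stream(truth, geometry, SensorModel(nominal_rate=150.0), seed=2)
        trajs = angle_trajectories(rec)
        expected = truth.angles_at(rec.times)
        for joint in ("middle_mcp", "middle_pip", "middle_dip"):
            assert np.max(np.abs(trajs[joint].angles - expected[joint])) < 1e-9

    def test_frames_with_missing_landmarks_are_skipped(self, geometry):
        rec = pose_recording(geometry, {"index_pip": 25.0}, n_frames=5)
        rec.positions[2, rec.landmark_index("index_dip")] = np.nan
        trajs = angle_trajectories(rec, joints=("index_pip", "index_mcp"))
        assert trajs["index_pip"].times.size == 4      # frame 2 dropped
        assert trajs["index_mcp"].times.size == 5      # unaffected joint keeps all

    def test_entirely_missing_joint_raises(self, geometry):
        rec = pose_recording(geometry, {})
        rec.positions[:, rec.landmark_index("pinky_tip")] = np.nan
        with pytest.raises(InsufficientDataError):
            angle_trajectories(rec, joints=("pinky_dip",))


class TestSegmentLengths:
    def test_three_four_five_distance(self, geometry):
        rec = pose_recording(geometry, {})
        i_mcp = rec.landmark_index("index_mcp")
        i_pip = rec.landmark_index("index_pip")
        rec.positions[:, i_pip] = rec.positions[:, i_mcp] + np.array([3.0, 4.0, 0.0])
        records = {(r.finger, r.segment): r for r in segment_lengths(rec)}
        assert records[("index", "proximal")].mean == pytest.approx(5.0, abs=1e-12)

    def test_noiseless_recording_reproduces_geometry_exactly(self, geometry):
        truth = TruthTrajectories(TaskProfile.static())
        rec = render_stream(truth, geometry, SensorModel(nominal_rate=150.0), seed=0)
        for r in segment_lengths(rec):
            assert r.mean == pytest.approx(geometry.length(r.finger, r.segment), abs=1e-9)
            assert r.sd < 1e-9

    def test_identical_points_flagged_degenerate(self, geometry):
        rec = pose_recording(geometry, {})
        rec.positions[:, rec.landmark_index("ring_tip")] = \
            rec.positions[:, rec.landmark_index("ring_dip")]
        records = {(r.finger, r.segment): r for r in segment_lengths(rec)}
        row = records[("ring", "distal")]
        assert row.mean == 0.0 and row.degenerate

    def test_noisy_static_recovers_geometry_within_sampling_error(self, geometry):
        noise = 0.5
        truth = TruthTrajectories(TaskProfile.static(duration=4.0))
        rec = render_stream(truth, geometry,
                            SensorModel(nominal_rate=150.0, positional_noise_sd=noise),
                            seed=9)
        n = rec.n_frames
        for r in segment_lengths(rec):
            true = geometry.length(r.finger, r.segment)
            # distance of two points with isotropic noise: sd ~ sqrt(2)*noise
            assert abs(r.mean - true) < 3.0 * math.sqrt(2.0) * noise / math.sqrt(n) + 0.01

    def test_reference_reporting_drops_non_thumb_metacarpals(self, geometry):
        rec = pose_recording(geometry, {})
        kept = {(r.finger, r.segment) for r in segment_lengths(rec, metacarpals="thumb_only")}
        assert ("thumb", "metacarpal") in kept
        assert ("index", "metacarpal") not in kept


class TestRom:
    def traj(self, angles, times=None):
        angles = np.asarray(angles, float)
        times = np.arange(angles.size) / 150.0 if times is None else times
        return AngleTrajectory(joint="index_mcp", times=times, angles=angles)

    def test_constant_trajectory_has_zero_rom(self):
        assert rom(self.traj(np.full(10, 33.0))).rom == 0.0

    def test_worked_extrema_example(self):
        """A trajectory attaining max 78.01 and min 9.62 has ROM 68.39."""
        t = np.linspace(0, 1, 201)  # grid contains the mid-cycle peak exactly
        angles = 9.62 + (78.01 - 9.62) * 0.5 * (1 - np.cos(2 * np.pi * t))
        record = rom(self.traj(angles, times=t))
        assert record.angle_max == pytest.approx(78.01, abs=1e-12)
        assert record.angle_min == pytest.approx(9.62, abs=1e-12)
        assert record.rom == pytest.approx(68.39, abs=1e-9)

    def test_raised_cosine_rom_is_amplitude_minus_rest(self):
        truth = TruthTrajectories(
            TaskProfile(task="t", amplitude={"index_mcp": 80.0},
                        rest_angle={"index_mcp": 5.0}, n_cycles=3))
        record = rom(self.traj(truth.angles["index_mcp"], times=truth.times))
        assert record.rom == pytest.approx(75.0, abs=1e-9)

    def test_rom_invariant_to_time_reparameterisation(self):
        angles = np.array([5.0, 20.0, 60.0, 80.0, 40.0, 5.0])
        slow = self.traj(angles, times=np.array([0, 1, 2, 3, 4, 5.0]))
        fast = self.traj(angles, times=np.array([0, 0.1, 0.15, 0.3, 0.8, 0.9]))
        assert rom(slow).rom == rom(fast).rom

    def test_empty_trajectory_rejected(self):
        with pytest.raises(InsufficientDataError):
            rom(self.traj(np.array([12.0])))


class TestRomDifference:
    @pytest.mark.parametrize("reference,test,expected", [
        (72.15, 43.86, 28.29),    # thumb flexion, IP
        (42.44, 54.10, -11.66),   # thumb abduction, CMC
        (50.0, 50.0, 0.0),
    ])
    def test_reference_minus_test_convention(self, reference, test, expected):
        assert rom_difference(reference, test) == pytest.approx(expected, abs=1e-9)

    def test_negative_rom_rejected(self):
        with pytest.raises(ValidationError):
            rom_difference(-1.0, 3.0)
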