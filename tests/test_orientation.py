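import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy.spatial.transform import Rotation

from hometwin import orientation as ori
from hometwin.synth.motion import random_rotation

from conftest import wrap_deg


def _stream(times, rots, sensor="x", rate=100.0):
    return ori.QuaternionStream.from_rotations(sensor, times, rots, rate)


class TestCalibrateSegment:
    def test_identity_when_gravities_match_convention(self):
        cal = ori.calibrate_segment(
            ori.POSE1_GRAVITY_SEG, ori.POSE2_GRAVITY_SEG, "thorax"
        )
        assert np.allclose(cal.matrix, np.eye(3), atol=1e-12)
        assert cal.residual_deg < 1e-9

    def test_recovers_known_mounting_rotation(self):
        """Gravity vectors pre-rotated by a known R are mapped back by R^T."""
        rng = np.random.default_rng(11)
        for _ in range(20):
            r = random_rotation(rng)
            a1 = r.inv().apply(ori.POSE1_GRAVITY_SEG)
            a2 = r.inv().apply(ori.POSE2_GRAVITY_SEG)
            cal = ori.calibrate_segment(a1, a2)
            assert np.max(np.abs(cal.matrix - r.as_matrix())) < 1e-9
            assert cal.residual_deg < 1e-6

    def test_collinear_poses_rejected(self):
        g1 = np.array([0.0, 1.0, 0.0])
        g2 = Rotation.from_euler("x", 5, degrees=True).apply(g1)
        with pytest.raises(ValueError, match="degenerate calibration poses"):
            ori.calibrate_segment(g1, g2)


class TestResampleSlerp:
    def test_constant_stream_stays_constant(self):
        rot = Rotation.from_euler("y", 30, degrees=True)
        times = np.arange(11) / 10.0
        s = _stream(times, Rotation.concatenate([rot] * 11))
        out = ori.resample_slerp(s, 100.0)
        rel = out.rotations.inv() * rot
        assert np.max(rel.magnitude()) < 1e-12

    def test_geodesic_midpoint(self):
        rots = Rotation.from_euler("z", [[0.0], [90.0]], degrees=True)
        s = _stream(np.array([0.0, 1.0]), rots)
        out = ori.resample_slerp(s, 2.0)  # grid 0, 0.5, 1
        mid = out.rotations[1].as_euler("zyx", degrees=True)
        assert mid[0] == pytest.approx(45.0, abs=1e-9)

    def test_uniform_velocity_preserved(self):
        """Angular speed of a constant-rate rotation is constant after
        resampling (finite-difference check)."""
        t = np.arange(0, 2.005, 0.01)
        rots = Rotation.from_euler("x", (40.0 * t)[:, None], degrees=True)
        s = _stream(t, rots)
        out = ori.resample_slerp(s, 225.0)
        rel = out.rotations[:-1].inv() * out.rotations[1:]
        speeds = rel.magnitude() * 225.0
        assert np.max(np.abs(speeds - np.radians(40.0))) < 1e-6

    def test_empty_or_single_sample_rejected(self):
        s = _stream(np.array([0.0]), Rotation.identity(1))
        with pytest.raises(ValueError):
            ori.resample_slerp(s, 10.0)

    def test_hemisphere_canonicalization(self):
        rng = np.random.default_rng(5)
        rots = Rotation.from_rotvec(np.cumsum(rng.normal(0, 0.05, (50, 3)), axis=0))
        q = rots.as_quat()[:, [3, 0, 1, 2]]
        q[::3] *= -1.0  # scramble hemispheres
        s = ori.QuaternionStream("x", np.arange(50) / 10.0, q, 10.0).canonicalized()
        dots = np.sum(s.quat_wxyz[1:] * s.quat_wxyz[:-1], axis=1)
        assert np.all(dots >= 0)


class TestJointRotation:
    def test_identity_for_equal_streams(self):
        r = random_rotation(np.random.default_rng(1), 10)
        rel = ori.joint_rotation(r, r)
        assert np.max(rel.magnitude()) < 1e-12

    def test_recovers_known_offset(self):
        parent = random_rotation(np.random.default_rng(2), 10)
        off = Rotation.from_euler("z", 30, degrees=True)
        child = parent * off
        rel = ori.joint_rotation(parent, child)
        assert np.max((rel * off.inv()).magnitude()) < 1e-12

    def test_matches_matrix_product_oracle(self):
        rng = np.random.default_rng(3)
        parent = random_rotation(rng, 100)
        child = random_rotation(rng, 100)
        rel = ori.joint_rotation(parent, child)
        expected = np.einsum("nji,njk->nik", parent.as_matrix(), child.as_matrix())
        assert np.max(np.abs(rel.as_matrix() - expected)) < 1e-12

    def test_grid_mismatch_rejected(self):
        r = random_rotation(np.random.default_rng(4), 5)
        with pytest.raises(ValueError, match="grid"):
            ori.joint_rotation(r, r, np.arange(5.0), np.arange(5.0) + 0.1)


class TestEulerDecompositions:
    def test_shoulder_identity(self):
        ang, mask = ori.euler_shoulder(Rotation.identity(1))
        assert bool(mask[0])
        assert np.allclose(ang[0], [0.0, 0.0, 0.0], atol=1e-9)

    def test_shoulder_pure_elevation_in_anterior_plane(self):
        """Elevation of 30 deg in the 90-deg (anterior sagittal) plane."""
        rot = Rotation.from_euler("YXY", [90.0, 30.0, 0.0], degrees=True)
        ang, mask = ori.euler_shoulder(rot)
        assert not mask
        assert np.allclose(ang, [90.0, 30.0, 0.0], atol=1e-9)

    def test_shoulder_roundtrip_oracle(self):
        """Decompose -> recompose is the identity for 10^3 random rotations
        away from zero elevation."""
        rng = np.random.default_rng(7)
        worst = 0.0
        n = 0
        while n < 1000:
            r = random_rotation(rng, 1)
            ang, mask = ori.euler_shoulder(r)
            if mask[0] or ang[0][1] < 5.0:
                continue
            n += 1
            back = Rotation.from_euler("YXY", ang[0], degrees=True)
            worst = max(worst, float((r * back.inv()).magnitude()[0]))
        assert worst < 1e-9

    def test_lower_identity_and_pure_flexion(self):
        ang, _ = ori.euler_lower(Rotation.identity(1))
        assert np.allclose(ang[0], 0.0, atol=1e-12)
        rot = Rotation.from_euler("ZXY", [91.8, 0.0, 0.0], degrees=True)
        ang, mask = ori.euler_lower(rot)
        assert not mask
        assert ang[0] == pytest.approx(91.8, abs=1e-9)
        assert abs(ang[1]) < 1e-9 and abs(ang[2]) < 1e-9

    def test_lower_roundtrip_oracle(self):
        rng = np.random.default_rng(8)
        worst = 0.0
        n = 0
        while n < 1000:
            r = random_rotation(rng, 1)
            ang, mask = ori.euler_lower(r)
            if mask[0]:
                continue
            n += 1
            back = Rotation.from_euler("ZXY", ang[0], degrees=True)
            worst = max(worst, float((r * back.inv()).magnitude()[0]))
        assert worst < 1e-9

    def test_lower_gimbal_flagged_and_interpolated(self):
        angles = np.zeros((5, 3))
        angles[:, 0] = [10.0, 11.0, 12.0, 13.0, 14.0]
        angles[2, 1] = 89.5  # within 1 deg of gimbal
        rots = Rotation.from_euler("ZXY", angles, degrees=True)
        ang, mask = ori.euler_lower(rots)
        assert mask[2] and not mask[1]
        assert ang[2, 0] == pytest.approx(12.0, abs=0.5)

    def test_trunk_inclination_conventions(self):
        upright = Rotation.identity(1)
        ang, _ = ori.trunk_inclination(upright)
        assert ang[0][1] == pytest.approx(0.0, abs=1e-9)
        flexed = Rotation.from_euler("YXY", [0.0, 90.0, 0.0], degrees=True)
        ang, mask = ori.trunk_inclination(flexed)
        assert not mask
        assert ang[1] == pytest.approx(90.0, abs=1e-9)

    def test_plane_carried_forward_at_low_elevation(self):
        seq = Rotation.from_euler(
            "YXY",
            [[40.0, 20.0, 5.0], [40.0, 0.2, 5.0], [40.0, 20.0, 5.0]],
            degrees=True,
        )
        ang, mask = ori.euler_shoulder(seq)
        assert mask[1] and not mask[0]
        assert ang[1, 0] == pytest.approx(40.0, abs=1e-9)  # carried plane


@given(st.integers(min_value=0, max_value=10_000))
def test_quaternion_stream_rejects_non_unit(seed):
    rng = np.random.default_rng(seed)
    q = rng.normal(size=(5, 4))
    q /= np.linalg.norm(q, axis=1, keepdims=True)
    q[2] *= 1.01
    with pytest.raises(ValueError, match="unit norm"):
        ori.QuaternionStream("x", np.arange(5.0), q, 1.0)


class TestEndToEndRecovery:
    def test_noiseless_recovery_and_mounting_invariance(self, truth, schedule):
        """Noiseless sensing with arbitrary mounting recovers truth within
        0.1 deg RMSE; redrawing the mounting changes nothing (< 0.1 deg)."""
        from hometwin.cohort import angle_rmse_by_channel, build_subject
        from hometwin.config import RunConfig
        from hometwin.synth import generate_layout

        cfg = RunConfig(n_subjects=1, duration_s=300.0, imu_noise_deg=0.0)
        lay = generate_layout(cfg.root_seed)
        a = build_subject(lay, cfg, "s01", 5, 5, 5)
        assert angle_rmse_by_channel(a).max() < 0.1

        b = build_subject(lay, cfg, "s01", 5, 5, 5, mounting_seed=99)
        n = min(a.n_common, b.n_common)
        diff = wrap_deg(a.angles.angles[:n] - b.angles.angles[:n])
        assert np.sqrt((diff**2).mean(axis=0)).max() < 0.1
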