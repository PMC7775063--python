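"""15-link kinematics: model build, forward kinematics, trajectories, contact."""

from dataclasses import replace

import numpy as np
import pytest

from saurogait.biomech import (
    TABLE2_LINKS,
    ankle_accommodation,
    build_biomech_model,
    forward_kinematics,
    ground_height,
    joint_trajectory,
    nominal_leg_z,
    rot,
    stance_windows,
    step_gait,
)
from saurogait.planar import SineParams


class TestBuildModel:
    def test_total_mass_is_printed_column_sum(self, biomech_model):
        assert biomech_model.total_mass == pytest.approx(10.14e-3, abs=1e-12)

    def test_individual_links(self, biomech_model):
        assert biomech_model.link_masses[0] == pytest.approx(3.6e-3)
        assert biomech_model.link_lengths[2] == pytest.approx(84e-3)

    def test_paired_legs_share_geometry(self, biomech_model):
        # thigh pair (links 10 and 13) and the other leg pairs
        for a, b in ((3, 6), (4, 7), (5, 8), (9, 12), (10, 13), (11, 14)):
            assert biomech_model.link_lengths[a] == biomech_model.link_lengths[b]
            assert biomech_model.link_masses[a] == biomech_model.link_masses[b]

    def test_missing_link_raises(self):
        table = dict(TABLE2_LINKS)
        del table["body7"]
        with pytest.raises(ValueError, match="body7"):
            build_biomech_model(table)


def _literal_fk(model, q):
    """Verbatim transcription of the printed center-of-mass position chain
    (independent oracle for the tree-based forward kinematics)."""
    l = np.concatenate([[np.nan], model.link_lengths])  # 1-based
    sx, sy = model.shoulder_x, model.shoulder_y
    px, py = model.pelvic_x, model.pelvic_y
    Q = {i + 1: q[i] for i in range(33)}
    Rz = lambda i: rot("z", Q[i])
    Rx = lambda i: rot("x", Q[i])
    Ry = lambda i: rot("y", Q[i])
    base = np.array([Q[1], Q[2], 0.0])
    v = lambda x, y=0.0, z=0.0: np.array([x, y, z])

    X = {}
    X[1] = base + Rz(3) @ v(l[1] / 2)
    X[2] = X[1] + Rz(3) @ (v(l[1] / 2) + Rz(4) @ v(l[2] / 2))
    X[3] = X[2] + Rz(3) @ Rz(4) @ (v(l[2] / 2) + Rz(5) @ v(l[3] / 2))
    RL = Rz(3) @ Rz(6) @ Rx(7) @ Ry(8)
    X[4] = base + Rz(3) @ v(l[1] / 2 + sx, -sy) + RL @ v(0, -l[4] / 2)
    X[5] = X[4] + RL @ (v(0, -l[4] / 2) + Rz(9) @ v(-l[5] / 2))
    X[6] = X[5] + RL @ Rz(9) @ (
        v(-l[5] / 2) + Rz(10) @ Rx(11) @ Ry(12) @ v(-l[6] / 2)
    )
    RR = Rz(3) @ Rz(13) @ Rx(14) @ Ry(15)
    X[7] = base + Rz(3) @ v(l[1] / 2 + sx, sy) + RR @ v(0, l[7] / 2)
    X[8] = X[7] + RR @ (v(0, l[7] / 2) + Rz(16) @ v(-l[8] / 2))
    X[9] = X[8] + RR @ Rz(16) @ (
        v(-l[8] / 2) + Rz(17) @ Rx(18) @ Ry(19) @ v(-l[9] / 2)
    )
    HL = Rz(3) @ Rz(4) @ Rz(20) @ Rx(21) @ Ry(22)
    X[10] = (
        base + Rz(3) @ v(l[1]) + Rz(3) @ Rz(4) @ v(l[2] / 2 + px, -py)
        + HL @ v(0, -l[10] / 2)
    )
    X[11] = X[10] + HL @ (v(0, -l[10] / 2) + Rz(23) @ v(l[11] / 2))
    X[12] = X[11] + HL @ Rz(23) @ (
        v(l[11] / 2) + Rz(24) @ Rx(25) @ Ry(26) @ v(l[12] / 2)
    )
    HR = Rz(3) @ Rz(4) @ Rz(27) @ Rx(28) @ Ry(29)
    X[13] = (
        base + Rz(3) @ v(l[1]) + Rz(3) @ Rz(4) @ v(l[2] / 2 + px, py)
        + HR @ v(0, l[13] / 2)
    )
    X[14] = X[13] + HR @ (v(0, l[13] / 2) + Rz(30) @ v(l[14] / 2))
    X[15] = X[14] + HR @ Rz(30) @ (
        v(l[14] / 2) + Rz(31) @ Rx(32) @ Ry(33) @ v(l[15] / 2)
    )
    return np.stack([X[i] for i in range(1, 16)])


class TestForwardKinematics:
    def test_zero_pose_anterior_body(self, biomech_model):
        fk = forward_kinematics(biomech_model, np.zeros(33))
        assert np.allclose(fk.com[0] * 1e3, [33.0, 0.0, 0.0], atol=1e-12)
        assert np.allclose(fk.com[1] * 1e3, [87.0, 0.0, 0.0], atol=1e-12)

    def test_matches_literal_equation_oracle(self, biomech_model, rng):
        for _ in range(200):
            q = rng.uniform(-1.2, 1.2, 33)
            fk = forward_kinematics(biomech_model, q)
            oracle = _literal_fk(biomech_model, q)
            assert np.abs(fk.com - oracle).max() < 1e-10

    def test_rigid_segment_lengths(self, biomech_model, rng):
        l = biomech_model.link_lengths
        for _ in range(10):
            q = rng.uniform(-1, 1, 33)
            fk = forward_kinematics(biomech_model, q)
            lm = fk.landmarks
            assert np.linalg.norm(lm["knee_left"] - lm["hip_left"]) == pytest.approx(
                l[9], abs=1e-12
            )
            assert np.linalg.norm(lm["ankle_left"] - lm["knee_left"]) == pytest.approx(
                l[10], abs=1e-12
            )
            assert np.linalg.norm(lm["tiptoe_left"] - lm["ankle_left"]) == pytest.approx(
                l[11], abs=1e-12
            )


class TestJointTrajectory:
    def test_zero_amplitude_yields_constant(self, trajectory):
        p = replace(trajectory, knee=SineParams(0.0, 0.5, np.deg2rad(-35.0)))
        vals = [joint_trajectory(t, p)[0][22] for t in np.linspace(0, p.period, 9)]
        assert np.allclose(vals, np.deg2rad(-35.0))

    def test_right_shoulder_y_carries_pi_shift(self, trajectory):
        p = replace(trajectory, hip_roll=SineParams(np.deg2rad(25.0), 0.7, 0.0))
        sines = p.right_sines()
        t = np.linspace(0, p.period, 11)
        expected = np.deg2rad(25.0) * np.sin(
            2 * np.pi * t / p.period + 0.7 + np.pi
        )
        assert np.allclose(sines[29](t, p.period), expected, atol=1e-12)

    def test_right_leg_mirrors_left_half_period_later(self, trajectory):
        t = np.linspace(0, trajectory.period, 23)
        th = t + trajectory.period / 2
        left = trajectory.left_sines()
        right = trajectory.right_sines()
        Tp = trajectory.period
        # z/x rotations and the knee are negated; the y rotation is kept
        for jl, jr, sign in ((20, 27, -1), (21, 28, -1), (23, 30, -1), (22, 29, 1)):
            assert np.allclose(right[jr](t, Tp), sign * left[jl](th, Tp), atol=1e-12)

    def test_analytic_rates_match_finite_differences(self, trajectory):
        h = 1e-7
        for t in (0.004, 0.013, 0.027):
            q, qd, qdd = joint_trajectory(t, trajectory)
            qp, _, _ = joint_trajectory(t + h, trajectory)
            qm, _, _ = joint_trajectory(t - h, trajectory)
            # sine-driven and constrained coordinates (ankles excluded: their
            # rates are not produced analytically)
            idx = [2, 3, 4, 19, 20, 21, 22, 26, 27, 28, 29]
            assert np.allclose(qd[idx], (qp - qm)[idx] / (2 * h), atol=1e-5)
            assert np.allclose(
                qdd[idx], (qp + qm - 2 * q)[idx] / h**2, rtol=1e-3, atol=1e-3
            )


class TestGroundAndAnkle:
    def test_closed_form_leg_height_matches_fk(self, biomech_model, trajectory, rng):
        ts = rng.uniform(0, trajectory.period, 6)
        for side in ("left", "right"):
            az, _, _ = nominal_leg_z(biomech_model, trajectory, ts, side)
            for k, tk in enumerate(ts):
                q, _, _ = joint_trajectory(tk, trajectory)
                fk = forward_kinematics(biomech_model, q)
                assert fk.landmarks[f"ankle_{side}"][2] == pytest.approx(
                    az[k], abs=1e-12
                )

    def test_ground_between_tiptoe_and_ankle_minima(self, biomech_model, trajectory):
        zg = ground_height(biomech_model, trajectory)
        ts = np.linspace(0, trajectory.period, 1500, endpoint=False)
        ankle, _center, tip = nominal_leg_z(biomech_model, trajectory, ts)
        assert tip.min() < zg < ankle.min()

    def test_growing_envelope_never_raises_ground(self, biomech_model, trajectory):
        zg = ground_height(biomech_model, trajectory)
        bigger = replace(
            trajectory,
            hip_roll=SineParams(
                2 * trajectory.hip_roll.amplitude,
                trajectory.hip_roll.phase,
                trajectory.hip_roll.offset,
            ),
        )
        assert ground_height(biomech_model, bigger) <= zg + 1e-12

    def test_accommodation_is_identity_on_ground(self, biomech_model, trajectory):
        zg = ground_height(biomech_model, trajectory)
        # a swing-phase instant: the nominal foot is above the ground
        windows = stance_windows(biomech_model, trajectory, zg)
        t_on, t_off = windows["left"][0]
        t_swing = (t_off + trajectory.period + t_on) / 2 % trajectory.period
        q, _, _ = joint_trajectory(t_swing, trajectory, biomech_model)
        q2 = ankle_accommodation(biomech_model, q, zg, "left")
        assert np.allclose(q, q2)

    def test_accommodation_pins_foot_end_to_ground(self, biomech_model, trajectory):
        zg = ground_height(biomech_model, trajectory)
        windows = stance_windows(biomech_model, trajectory, zg)
        t_on, t_off = windows["left"][0]
        t_mid = 0.5 * (t_on + t_off)
        q, _, _ = joint_trajectory(t_mid, trajectory, biomech_model)
        fk = forward_kinematics(biomech_model, q)
        assert fk.landmarks["tiptoe_left"][2] < zg  # nominal foot penetrates
        q2 = ankle_accommodation(biomech_model, q, zg, "left")
        fk2 = forward_kinematics(biomech_model, q2)
        assert fk2.landmarks["tiptoe_left"][2] == pytest.approx(zg, abs=1e-9)
        # only the ankle pitch moved
        changed = np.flatnonzero(~np.isclose(q, q2))
        assert list(changed) == [25]

    def test_posture_restored_after_liftoff(self, biomech_model, trajectory):
        """The nominal (pre-contact) ankle posture returns once the foot
        leaves the ground."""
        zg = ground_height(biomech_model, trajectory)
        windows = stance_windows(biomech_model, trajectory, zg)
        t_on, t_off = windows["left"][0]
        q_pre, _, _ = joint_trajectory(t_on - 0.1 * trajectory.period, trajectory,
                                       biomech_model)
        q_post, _, _ = joint_trajectory(t_off + 0.1 * trajectory.period, trajectory,
                                        biomech_model)
        # both are the forward-facing solution; accommodation leaves them be
        for q in (q_pre, q_post):
            assert np.allclose(q, ankle_accommodation(biomech_model, q, zg, "left"))

    def test_unreachable_ground_raises(self, biomech_model, trajectory):
        q, _, _ = joint_trajectory(0.0, trajectory, biomech_model)
        # a ground plane above the ankle's reach cannot be met by any pitch
        with pytest.raises(ValueError, match="unreachable"):
            ankle_accommodation(biomech_model, q, 0.05, "left")


@pytest.fixture(scope="module")
def trace(biomech_model, trajectory):
    return step_gait(biomech_model, trajectory, n_strides=4, steps_per_period=300)


class TestStepGait:
    def test_stance_tiptoe_is_anchored(self, trace):
        for side, code, tip in (("left", 0, trace.tiptoe_left),
                                ("right", 1, trace.tiptoe_right)):
            idx = np.flatnonzero(trace.contact == code)
            segs = np.split(idx, np.flatnonzero(np.diff(idx) > 1) + 1)
            for seg in segs:
                if len(seg) < 2:
                    continue
                assert np.ptp(tip[seg, 0]) < 1e-9
                assert np.ptp(tip[seg, 1]) < 1e-9
                assert np.abs(tip[seg, 2] - trace.ground_height).max() < 1e-9

    def test_footfalls_alternate_half_period_apart(self, trace):
        lefts = [t for t, side, _ in trace.touchdowns if side == "left"]
        rights = [t for t, side, _ in trace.touchdowns if side == "right"]
        assert len(lefts) >= 3 and len(rights) >= 3
        half = trace.period / 2
        for tl, tr in zip(lefts, rights):
            assert abs((tr - tl) - half) < trace.period / 50

    def test_zero_leg_amplitude_is_ballistic_with_low_ground(
        self, biomech_model, trajectory
    ):
        p = replace(
            trajectory,
            hip_swing=SineParams(0.0, 0.0, 0.0),
            hip_lift=SineParams(0.0, 0.0, np.deg2rad(40.0)),
            hip_roll=SineParams(0.0, 0.0, 0.0),
            knee=SineParams(0.0, 0.0, np.deg2rad(-35.0)),
        )
        tr = step_gait(biomech_model, p, n_strides=2, steps_per_period=100,
                       z_g=-0.2)
        assert (tr.contact == -1).all()
        v = np.diff(tr.com[:, 0]) / np.diff(tr.t)
        assert np.allclose(v, 4.0, atol=1e-9)

    def test_body_frame_trajectories_are_periodic(self, trace):
        """After the first stride the gait repeats exactly: landmark
        positions one period apart differ by a constant translation."""
        n = 300
        hip = trace.hip_left
        d1 = hip[2 * n] - hip[n]
        d2 = hip[3 * n] - hip[2 * n]
        assert np.abs(d1 - d2).max() < 1e-6
        tipz = trace.tiptoe_left[:, 2]
        assert np.abs(tipz[n:2 * n] - tipz[2 * n:3 * n]).max() < 1e-9

    def test_body_height_constant(self, trace):
        assert np.ptp(trace.hip_left[:, 2]) < 1e-12
        # the COM height wiggles only through the accommodated feet (~1e-5 m)
        assert np.ptp(trace.com[:, 2]) < 1e-4


class TestMirrorSymmetry:
    def test_swapping_sides_reflects_trajectories(self, biomech_model, trajectory):
        """With the y-offsets mirrored, the right-leg chain is the exact
        reflection of the left-leg chain half a period later."""
        Tp = trajectory.period
        for t in np.linspace(0, Tp, 7, endpoint=False):
            q, _, _ = joint_trajectory(t, trajectory, biomech_model)
            qh, _, _ = joint_trajectory(t + Tp / 2, trajectory, biomech_model)
            fk = forward_kinematics(biomech_model, q)
            fkh = forward_kinematics(biomech_model, qh)
            # compare in the pelvis frame (the prescribed pelvic sine is
            # antisymmetric under the half-period shift)
            left = fk.landmarks["tiptoe_left"] - fk.landmarks["hip_left"]
            right = fkh.landmarks["tiptoe_right"] - fkh.landmarks["hip_right"]
            R = forward_kinematics(biomech_model, q).rotations[4]
            Rh = forward_kinematics(biomech_model, qh).rotations[4]
            l_local = R.T @ left
            r_local = Rh.T @ right
            assert np.allclose(l_local * [1, -1, 1], r_local, atol=1e-9)
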