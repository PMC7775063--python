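"""Three-link planar model: construction, chain algebra, dynamics, simulation."""

import numpy as np
import pytest

from saurogait.planar import (
    GaitSchedule,
    GrfProfile,
    PdGains,
    SineParams,
    TABLE1_MORPHOMETRICS,
    build_planar_model,
    chain_constraint_matrices,
    com_offsets,
    cylinder_yaw_inertia,
    grf_profile,
    internal_forces,
    pd_torque,
    planar_forward_dynamics,
    simulate_stride,
)


class TestBuildModel:
    def test_total_mass_matches_printed_table(self, planar_model):
        assert planar_model.total_mass == pytest.approx(0.010, abs=1e-12)

    def test_tail_inertia_cylinder_rule(self, planar_model):
        # m (l^2/12 + r^2/4) for the 2 g, 84 mm x 6 mm tail
        assert planar_model.yaw_inertias[2] == pytest.approx(1.1805e-6, rel=1e-6)

    def test_disc_limit_of_cylinder_rule(self):
        assert cylinder_yaw_inertia(0.002, 0.0, 0.006) == pytest.approx(
            0.002 * 0.003**2 / 4.0
        )

    @pytest.mark.parametrize("key", ["tail_mass_g", "anterior_body_length_mm"])
    def test_missing_or_nonpositive_field_raises_with_name(self, key):
        table = dict(TABLE1_MORPHOMETRICS)
        del table[key]
        with pytest.raises(ValueError, match=key):
            build_planar_model(table)
        table = dict(TABLE1_MORPHOMETRICS)
        table[key] = -1.0
        with pytest.raises(ValueError, match=key):
            build_planar_model(table)


class TestChainConstraints:
    def test_straight_chain_y_closure_is_zero(self, planar_model):
        q = np.zeros(3)
        C, L = chain_constraint_matrices(planar_model)
        xy = com_offsets(planar_model, q)
        assert np.allclose(C @ xy[:, 1], 0.0, atol=1e-15)

    def test_straight_chain_first_gap(self, planar_model):
        # neighbouring COM spacing (l1 + l2) / 2 = 54 mm at zero angles
        q = np.zeros(3)
        C, _ = chain_constraint_matrices(planar_model)
        xy = com_offsets(planar_model, q)
        assert (C @ xy[:, 0])[0] == pytest.approx(0.054, abs=1e-15)

    def test_random_state_closure_residual(self, planar_model, rng):
        C, L = chain_constraint_matrices(planar_model)
        for _ in range(20):
            q = rng.uniform(-np.pi, np.pi, 3)
            xy = com_offsets(planar_model, q)
            rx = C @ xy[:, 0] - 0.5 * L @ np.cos(q)
            ry = C @ xy[:, 1] - 0.5 * L @ np.sin(q)
            assert np.linalg.norm(rx) < 1e-12
            assert np.linalg.norm(ry) < 1e-12


class TestInternalForces:
    def test_static_chain_zero_forces(self, planar_model):
        Fx, Fy = internal_forces(
            planar_model, np.zeros(3), np.zeros(3), np.zeros(3)
        )
        assert np.allclose(Fx, 0) and np.allclose(Fy, 0)

    def test_rigid_rotation_matches_centripetal_oracle(self, planar_model):
        """A straight chain spinning about its COM carries pin forces equal to
        the centripetal load of the outboard partial chain."""
        m = planar_model.link_masses
        q = np.zeros(3)
        omega = 7.0
        qdot = np.full(3, omega)
        qddot = np.zeros(3)
        Fx, Fy = internal_forces(planar_model, q, qdot, qddot)
        xy = com_offsets(planar_model, q)  # relative to system COM
        # oracle: joint force = sum over outboard links of m * omega^2 * r
        # (force on link i+1 from link i is +F_i by the sign convention)
        for joint in (0, 1):
            outboard = range(joint + 1, 3)
            oracle = -sum(m[i] * omega**2 * xy[i, 0] for i in outboard)
            assert Fx[joint] == pytest.approx(oracle, rel=1e-10, abs=1e-12)
            assert Fy[joint] == pytest.approx(0.0, abs=1e-12)

    def test_statics_with_external_force_closes_newton(self, planar_model, rng):
        q = rng.uniform(-1, 1, 3)
        fext = rng.normal(0, 0.1, 2)
        Fext_x = np.array([0.0, fext[0], 0.0])
        Fext_y = np.array([0.0, fext[1], 0.0])
        qdot = np.zeros(3)
        qddot = rng.normal(0, 10, 3)
        Fx, Fy = internal_forces(planar_model, q, qdot, qddot, Fext_x, Fext_y)
        # per-link Newton balance must reproduce accelerations consistent
        # with the constraint equations
        C, L = chain_constraint_matrices(planar_model)
        m = planar_model.link_masses
        ax = (Fext_x + C.T @ Fx) / m
        ay = (Fext_y + C.T @ Fy) / m
        assert np.allclose(
            C @ ax, -0.5 * L @ (np.cos(q) * qdot**2 + np.sin(q) * qddot), atol=1e-9
        )
        assert np.allclose(
            C @ ay, 0.5 * L @ (-np.sin(q) * qdot**2 + np.cos(q) * qddot), atol=1e-9
        )


def _lagrangian_oracle(model, q, qdot, u, grf, foot_vec, mz):
    """Independent forward dynamics via finite-difference Euler-Lagrange in
    minimal coordinates z = (Xc, Yc, q1, q2, q3)."""
    m = model.link_masses
    mt = m.sum()
    II = model.yaw_inertias

    def positions(z):
        com = z[:2]
        return com + com_offsets(model, z[2:])

    def mass_matrix(z):
        h = 1e-4
        J = np.zeros((6, 5))  # d(x1,y1,..,x3,y3)/dz
        for k in range(5):
            dz = np.zeros(5)
            dz[k] = h
            J[:, k] = (positions(z + dz) - positions(z - dz)).ravel() / (2 * h)
        M = np.zeros((5, 5))
        for i in range(3):
            Ji = J[2 * i : 2 * i + 2]
            M += m[i] * Ji.T @ Ji
        M[2:, 2:] += np.diag(II)
        return M

    z = np.concatenate([[0.0, 0.0], q])
    zdot = np.zeros(5)
    zdot[2:] = qdot
    # COM velocity follows from angle rates (links are chained to the COM)
    h = 1e-6
    M = mass_matrix(z)
    # Christoffel terms by finite differences of M
    hM = 1e-4  # larger step: the FD truncation error is what limits the oracle
    dM = np.zeros((5, 5, 5))
    for k in range(5):
        dz = np.zeros(5)
        dz[k] = hM
        dM[:, :, k] = (mass_matrix(z + dz) - mass_matrix(z - dz)) / (2 * hM)
    # M zdd + Mdot zd - 1/2 d(zd' M zd)/dz = Q
    Mdot = np.einsum("ijk,k->ij", dM, zdot)
    C_force = Mdot @ zdot - 0.5 * np.einsum("ilj,i,l->j", dM, zdot, zdot)
    # generalized forces: external grf at the material point of link 2 at the
    # foot, Mz on link 2, joint torques.  The force's virtual work uses the
    # full Jacobian of the link-2 COM (its COM-relative offset depends on all
    # coordinates through the mass-weighted mean).
    fx, fy = grf
    Q = np.zeros(5)
    J2 = np.zeros((2, 5))
    for k in range(5):
        dz = np.zeros(5)
        dz[k] = h
        J2[:, k] = (positions(z + dz)[1] - positions(z - dz)[1]) / (2 * h)
    Q += J2.T @ np.array([fx, fy])
    # lever arm from link-2 COM to the foot rotates with q2
    Q[3] += foot_vec[0] * fy - foot_vec[1] * fx + mz
    # joint torques map through the relative angles j1 = q2-q1, j2 = q3-q2
    Q[2] += -u[0]
    Q[3] += u[0] - u[1]
    Q[4] += u[1]
    zddot = np.linalg.solve(M, Q - C_force)
    return zddot[2:]


class TestForwardDynamics:
    def test_equilibrium_gives_zero_acceleration(self, planar_model):
        qdd = planar_forward_dynamics(
            planar_model, np.zeros(3), np.zeros(3), np.zeros(2)
        )
        assert np.allclose(qdd, 0.0, atol=1e-14)

    def test_ground_moment_changes_total_angular_momentum(self, planar_model):
        """The net rate of angular momentum about the system COM equals the
        applied ground moment (forces are zero)."""
        q = np.zeros(3)
        mz = 1e-3
        qdd = planar_forward_dynamics(
            planar_model, q, np.zeros(3), np.zeros(2), ground_moment=mz
        )
        II = planar_model.yaw_inertias
        m = planar_model.link_masses
        xy = com_offsets(planar_model, q)
        # accelerations of link COMs from qdd at rest (straight chain)
        Fx, Fy = internal_forces(planar_model, q, np.zeros(3), qdd)
        C, _ = chain_constraint_matrices(planar_model)
        ay = (C.T @ Fy) / m
        Ldot = float(II @ qdd + sum(m[i] * xy[i, 0] * ay[i] for i in range(3)))
        assert Ldot == pytest.approx(mz, rel=1e-9)

    def test_matches_lagrangian_oracle_on_random_states(self, planar_model, rng):
        for _ in range(100):
            q = rng.uniform(-1.5, 1.5, 3)
            qdot = rng.normal(0, 10, 3)
            u = rng.normal(0, 0.005, 2)
            grf = rng.normal(0, 0.1, 2)
            p = rng.normal(0, 0.03, 2)
            mz = rng.normal(0, 1e-3)
            qdd = planar_forward_dynamics(
                planar_model, q, qdot, u, grf=tuple(grf),
                foot_vector=tuple(p), ground_moment=mz,
            )
            oracle = _lagrangian_oracle(planar_model, q, qdot, u, grf, p, mz)
            denom = max(1.0, np.abs(oracle).max())
            assert np.abs(qdd - oracle).max() / denom < 1e-6

    def test_mirror_symmetry(self, planar_model, rng):
        q = rng.uniform(-1, 1, 3)
        qdot = rng.normal(0, 5, 3)
        u = rng.normal(0, 0.01, 2)
        fx, fy = 0.05, -0.08
        p = (0.02, -0.01)
        mz = 5e-4
        a = planar_forward_dynamics(planar_model, q, qdot, u, (fx, fy), p, mz)
        b = planar_forward_dynamics(
            planar_model, -q, -qdot, -u, (fx, -fy), (p[0], -p[1]), -mz
        )
        assert np.allclose(a, -b, rtol=1e-12, atol=1e-12)


class TestGrfProfile:
    def test_aerial_window_is_force_free(self):
        sched = GaitSchedule(stance_fraction=0.5)
        fx, fy, side = grf_profile(0.0, sched, GrfProfile())
        assert (fx, fy, side) == (0.0, 0.0, None)

    def test_fore_aft_impulse_vanishes_over_a_stride(self):
        sched = GaitSchedule()
        prof = GrfProfile()
        t = np.linspace(0, sched.period, 20001)
        fx = np.array([grf_profile(tk, sched, prof)[0] for tk in t])
        assert abs(np.trapezoid(fx, t)) < 1e-6

    def test_lateral_force_mirrors_across_half_period(self):
        sched = GaitSchedule()
        prof = GrfProfile()
        for t in np.linspace(0.012, 0.033, 7):
            fy1 = grf_profile(t, sched, prof)[1]
            fy2 = grf_profile(t + sched.period / 2, sched, prof)[1]
            assert fy1 == pytest.approx(-fy2, abs=1e-12)

    def test_lateral_force_points_toward_midline(self):
        sched = GaitSchedule()
        prof = GrfProfile()
        fx, fy, side = grf_profile(0.023, sched, prof)  # mid first half
        assert side == "right" and fy <= 0.0


class TestPdTorque:
    def test_zero_error_zero_torque(self):
        u = pd_torque((0.1, 0.2), (1.0, 2.0), (0.1, 0.2), (1.0, 2.0), PdGains())
        assert np.allclose(u, 0.0)

    def test_pure_proportional(self):
        gains = PdGains(kp=2.0, kd=0.0)
        u = pd_torque((0.3, -0.1), (0, 0), (0.1, 0.1), (5, -5), gains)
        assert np.allclose(u, [0.4, -0.4])


class TestSimulateStride:
    @staticmethod
    def _force_free(model, dt_frac):
        sched = GaitSchedule()
        und = (SineParams(np.deg2rad(15.0), 0.3), SineParams(np.deg2rad(10.0), -1.0))
        return simulate_stride(
            model, sched, GrfProfile(0, 0), PdGains(0, 0), und,
            mz_limit=0.0, n_periods=1, dt=sched.period / dt_frac,
        )

    @staticmethod
    def _angular_momentum(model, trace):
        from saurogait.planar import com_offsets

        II = model.yaw_inertias
        m = model.link_masses
        L = (II * trace.qdot).sum(axis=1)
        h = 1e-7
        for k in range(len(trace.t)):
            rel = com_offsets(model, trace.q[k])
            vel = (
                com_offsets(model, trace.q[k] + h * trace.qdot[k])
                - com_offsets(model, trace.q[k] - h * trace.qdot[k])
            ) / (2 * h)
            L[k] += float(
                (m * (rel[:, 0] * vel[:, 1] - rel[:, 1] * vel[:, 0])).sum()
            )
        return L

    def test_force_free_momentum_conserved(self, planar_model):
        """Angular momentum about the COM stays constant over a full period
        (RK4 drift is below roundoff at these step sizes)."""
        for frac in (250, 500):
            tr = self._force_free(planar_model, frac)
            L = self._angular_momentum(planar_model, tr)
            assert np.abs(L - L[0]).max() < 1e-9 * abs(L[0])

    def test_linear_momentum_constant_without_forces(self, planar_model):
        tr = self._force_free(planar_model, 400)
        assert np.allclose(tr.com_vel, tr.com_vel[0], atol=1e-12)

    def test_zero_undulation_keeps_joints_and_torques_small(self, planar_model):
        sched = GaitSchedule()
        # without external forcing the joints never leave their references
        quiet = simulate_stride(
            planar_model, sched, GrfProfile(0, 0), PdGains(),
            (SineParams(0.0), SineParams(0.0)), mz_limit=0.0,
            dt=sched.period / 500,
        )
        assert np.rad2deg(np.abs(quiet.joint_angles).max()) < 1e-9
        assert np.abs(quiet.torques).max() < 1e-9
        # with the gait's GRF/GRM the PD holds them within a few degrees
        tr = simulate_stride(
            planar_model, sched, GrfProfile(), PdGains(),
            (SineParams(0.0), SineParams(0.0)), dt=sched.period / 500,
        )
        assert np.rad2deg(np.abs(tr.joint_angles).max()) < 6.0

    def test_posterior_body_tracks_pelvic_reference(self, planar_model):
        sched = GaitSchedule()
        und = (SineParams(np.deg2rad(20.0), 0.0), SineParams(np.deg2rad(20.0), np.pi))
        tr = simulate_stride(
            planar_model, sched, GrfProfile(), PdGains(), und,
            n_periods=1, dt=sched.period / 500,
        )
        ref = sched.pelvic_reference(tr.t)
        err = np.rad2deg(np.abs(tr.q[:, 1] - ref).max())
        assert err < 4.0  # GRM servo active only during stance windows
        amp = np.rad2deg(np.ptp(tr.q[:, 1])) / 2
        assert amp == pytest.approx(20.0, abs=4.0)

    def test_chain_closure_along_trace(self, planar_model):
        sched = GaitSchedule()
        und = (SineParams(np.deg2rad(20.0), 0.0), SineParams(np.deg2rad(20.0), np.pi))
        tr = simulate_stride(planar_model, sched, GrfProfile(), PdGains(), und,
                             dt=sched.period / 500)
        C, L = chain_constraint_matrices(planar_model)
        for k in range(0, len(tr.t), 50):
            xy = tr.link_xy[k] - tr.com[k]
            rx = C @ xy[:, 0] - 0.5 * L @ np.cos(tr.q[k])
            ry = C @ xy[:, 1] - 0.5 * L @ np.sin(tr.q[k])
            assert max(np.abs(rx).max(), np.abs(ry).max()) < 1e-6
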