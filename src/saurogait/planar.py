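"""Horizontal-plane three-link dynamics of a bipedally running lizard.

The trunk is split into an anterior body, a posterior body (pelvis, carrying
the hind legs) and a tail, connected by two yaw joints (waist and tail base).
Roll, pitch and the vertical ground reaction are excluded: at high speed the
animal's body moves almost entirely in yaw, so the model lives in the
horizontal plane.  The stance foot transmits a fore-aft force, a lateral
force directed toward the midline, and a yaw ground-reaction moment (GRM);
the waist and tail joints are ideal torque sources driven by a PD controller
toward sinusoidal reference angles.

Conventions
-----------
* SI units internally (kg, m, s, N); constructors accept the field's mm/g.
* Global link angles ``q = (q1, q2, q3)`` are measured CCW from +x with the
  chain laid out head-to-tail along +x at ``q = 0`` (anterior body first),
  so the animal runs toward -x.
* Relative joint angles: waist ``j1 = q2 - q1``, tail ``j2 = q3 - q2``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "PlanarModel",
    "PlanarState",
    "PlanarForces",
    "GrfProfile",
    "GaitSchedule",
    "PdGains",
    "SineParams",
    "PlanarTrace",
    "cylinder_yaw_inertia",
    "build_planar_model",
    "chain_constraint_matrices",
    "com_offsets",
    "internal_forces",
    "planar_forward_dynamics",
    "grf_profile",
    "pd_torque",
    "simulate_stride",
    "TABLE1_MORPHOMETRICS",
]

#: Morphometrics of Callisaurus draconoides for the three-link model (mm / g).
TABLE1_MORPHOMETRICS: dict[str, float] = {
    "anterior_body_length_mm": 66.0,
    "posterior_body_length_mm": 42.0,
    "tail_length_mm": 84.0,
    "anterior_body_width_mm": 20.0,
    "posterior_body_width_mm": 20.0,
    "tail_width_mm": 6.0,
    "anterior_body_mass_g": 4.0,
    "posterior_body_mass_g": 4.0,
    "tail_mass_g": 2.0,
}


@dataclass(frozen=True)
class SineParams:
    """Amplitude/phase/offset triple for a sinusoidal joint reference.

    ``angle(t) = amplitude * sin(2*pi*t/period + phase) + offset``.
    Amplitude and offset are radians; the phase is wrapped to (-pi, pi].
    """

    amplitude: float
    phase: float = 0.0
    offset: float = 0.0

    def __post_init__(self) -> None:
        if self.amplitude < 0:
            raise ValueError("sine amplitude must be >= 0")
        wrapped = (self.phase + np.pi) % (2.0 * np.pi) - np.pi
        if wrapped == -np.pi:
            wrapped = np.pi
        object.__setattr__(self, "phase", float(wrapped))

    def __call__(self, t: float | np.ndarray, period: float) -> float | np.ndarray:
        w = 2.0 * np.pi / period
        return self.amplitude * np.sin(w * t + self.phase) + self.offset

    def deriv(self, t, period):
        w = 2.0 * np.pi / period
        return self.amplitude * w * np.cos(w * t + self.phase)

    def deriv2(self, t, period):
        w = 2.0 * np.pi / period
        return -self.amplitude * w * w * np.sin(w * t + self.phase)


@dataclass(frozen=True)
class PlanarModel:
    """Three-link planar lizard: anterior body, posterior body, tail."""

    link_lengths: np.ndarray
    link_widths: np.ndarray
    link_masses: np.ndarray
    yaw_inertias: np.ndarray
    foot_offset_distance: float = 0.038
    foot_offset_angle: float = np.deg2rad(45.0)

    def __post_init__(self):
        for name in ("link_lengths", "link_widths", "link_masses", "yaw_inertias"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != (3,):
                raise ValueError(f"{name} must have shape (3,)")
            if np.any(arr <= 0):
                raise ValueError(f"{name} entries must be strictly positive")
            object.__setattr__(self, name, arr)
        if self.foot_offset_distance <= 0:
            raise ValueError("foot_offset_distance must be positive")

    @property
    def total_mass(self) -> float:
        return float(self.link_masses.sum())


def cylinder_yaw_inertia(mass: float, length: float, width: float) -> float:
    """Yaw inertia of a homogeneous solid cylinder about a transverse COM axis.

    ``i = m (l^2/12 + r^2/4)`` with ``r = w/2``; for ``l = 0`` it reduces to
    the disc limit ``m r^2 / 4``.
    """
    r = 0.5 * width
    return mass * (length * length / 12.0 + r * r / 4.0)


def build_planar_model(
    morphometrics: Mapping[str, float] | None = None,
    *,
    foot_offset_distance_mm: float = 38.0,
    foot_offset_angle_deg: float = 45.0,
) -> PlanarModel:
    """Build a :class:`PlanarModel` from a morphometrics table in mm/g.

    The default table is the Callisaurus draconoides measurement set used
    throughout; yaw inertias follow the homogeneous-cylinder rule.
    """
    table = dict(TABLE1_MORPHOMETRICS if morphometrics is None else morphometrics)
    fields = [
        ("anterior_body_length_mm", "posterior_body_length_mm", "tail_length_mm"),
        ("anterior_body_width_mm", "posterior_body_width_mm", "tail_width_mm"),
        ("anterior_body_mass_g", "posterior_body_mass_g", "tail_mass_g"),
    ]
    values = []
    for group in fields:
        row = []
        for key in group:
            if key not in table:
                raise ValueError(f"missing morphometric field: {key}")
            v = float(table[key])
            if not np.isfinite(v) or v <= 0:
                raise ValueError(f"morphometric field {key} must be positive, got {v}")
            row.append(v)
        values.append(row)
    lengths = np.array(values[0]) * 1e-3
    widths = np.array(values[1]) * 1e-3
    masses = np.array(values[2]) * 1e-3
    inertias = np.array(
        [cylinder_yaw_inertia(m, l, w) for m, l, w in zip(masses, lengths, widths)]
    )
    return PlanarModel(
        link_lengths=lengths,
        link_widths=widths,
        link_masses=masses,
        yaw_inertias=inertias,
        foot_offset_distance=foot_offset_distance_mm * 1e-3,
        foot_offset_angle=np.deg2rad(foot_offset_angle_deg),
    )


# --------------------------------------------------------------------------
# chain kinematics


def chain_constraint_matrices(model: PlanarModel, state=None):
    """Signed incidence C (2x3) and length matrix L (2x3) of the chain.

    They encode the joint-closure conditions ``C x = (L/2) cos q`` and
    ``C y = (L/2) sin q`` relating neighbouring link COMs.
    """
    l1, l2, l3 = model.link_lengths
    C = np.array([[-1.0, 1.0, 0.0], [0.0, -1.0, 1.0]])
    L = np.array([[l1, l2, 0.0], [0.0, l2, l3]])
    return C, L


def com_offsets(model: PlanarModel, q: np.ndarray) -> np.ndarray:
    """Link COM positions (3, 2) relative to the system COM for angles q."""
    l = model.link_lengths
    e = np.stack([np.cos(q), np.sin(q)], axis=-1)
    r = np.zeros((3, 2))
    r[1] = r[0] + 0.5 * l[0] * e[0] + 0.5 * l[1] * e[1]
    r[2] = r[1] + 0.5 * l[1] * e[1] + 0.5 * l[2] * e[2]
    m = model.link_masses
    return r - (m[:, None] * r).sum(axis=0) / m.sum()


# --------------------------------------------------------------------------
# dynamics


def internal_forces(
    model: PlanarModel,
    q: np.ndarray,
    qdot: np.ndarray,
    qddot: np.ndarray,
    fext_x: np.ndarray | None = None,
    fext_y: np.ndarray | None = None,
):
    """Joint constraint forces (F_x, F_y) for the given chain accelerations.

    Eliminates the two pin-joint force pairs from the per-link Newton
    equations using the twice-differentiated closure constraints.
    """
    C, L = chain_constraint_matrices(model)
    m = model.link_masses
    Fx_ext = np.zeros(3) if fext_x is None else np.asarray(fext_x, float)
    Fy_ext = np.zeros(3) if fext_y is None else np.asarray(fext_y, float)
    K = (C / m) @ C.T
    s, c = np.sin(q), np.cos(q)
    rhs_x = -0.5 * L @ (c * qdot**2 + s * qddot) - (C / m) @ Fx_ext
    rhs_y = 0.5 * L @ (-s * qdot**2 + c * qddot) - (C / m) @ Fy_ext
    Fx = np.linalg.solve(K, rhs_x)
    Fy = np.linalg.solve(K, rhs_y)
    return Fx, Fy


def _assemble_rotational_system(model, q, qdot, fext_x, fext_y):
    """Return (A_eff, rhs_const, torque_map) with A_eff qdd = rhs_const + tau.

    tau collects joint torques (via the incidence transpose) and any external
    moments on individual links; the joint constraint forces, affine in qdd,
    have been eliminated into A_eff and rhs_const.
    """
    C, L = chain_constraint_matrices(model)
    m = model.link_masses
    K = (C / m) @ C.T
    Kinv = np.linalg.inv(K)
    s, c = np.sin(q), np.cos(q)
    Sin = np.diag(s)
    Cos = np.diag(c)
    Qx = -0.5 * Kinv @ L @ Sin
    Px = Kinv @ (-0.5 * L @ (c * qdot**2) - (C / m) @ fext_x)
    Qy = 0.5 * Kinv @ L @ Cos
    Py = Kinv @ (-0.5 * L @ (s * qdot**2) - (C / m) @ fext_y)
    LT = L.T
    A_eff = np.diag(model.yaw_inertias) - 0.5 * Sin @ LT @ Qx + 0.5 * Cos @ LT @ Qy
    rhs_const = 0.5 * s * (LT @ Px) - 0.5 * c * (LT @ Py)
    return A_eff, rhs_const


def planar_forward_dynamics(
    model: PlanarModel,
    q: np.ndarray,
    qdot: np.ndarray,
    joint_torques: np.ndarray,
    grf: tuple[float, float] = (0.0, 0.0),
    foot_vector: tuple[float, float] = (0.0, 0.0),
    ground_moment: float = 0.0,
) -> np.ndarray:
    """Angular accelerations of the three links.

    The ground reaction force ``grf`` acts on the posterior body at the
    stance foot, offset ``foot_vector = (p_x, p_y)`` from its COM;
    ``ground_moment`` is the yaw GRM, also on the posterior body.
    """
    q = np.asarray(q, float)
    qdot = np.asarray(qdot, float)
    u = np.asarray(joint_torques, float)
    fx, fy = grf
    px, py = foot_vector
    fext_x = np.array([0.0, fx, 0.0])
    fext_y = np.array([0.0, fy, 0.0])
    C, _ = chain_constraint_matrices(model)
    A_eff, rhs_const = _assemble_rotational_system(model, q, qdot, fext_x, fext_y)
    tau = C.T @ u
    tau[1] += px * fy - py * fx + ground_moment
    return np.linalg.solve(A_eff, rhs_const + tau)


# --------------------------------------------------------------------------
# gait schedule, GRF and control


@dataclass(frozen=True)
class GaitSchedule:
    """Timing of the alternating bipedal gait and the pelvic reference.

    Each half-period holds one stance (right foot first), a window of
    ``stance_fraction`` of the half-period centred within it.  The posterior
    body tracks ``pelvic_amplitude * sin(2 pi t / period)``.
    """

    period: float = 0.092
    stance_fraction: float = 0.5
    pelvic_amplitude: float = np.deg2rad(20.0)
    initial_speed: float = 4.0

    def __post_init__(self):
        if self.period <= 0:
            raise ValueError("period must be positive")
        if not 0.0 < self.stance_fraction <= 1.0:
            raise ValueError("stance_fraction must be in (0, 1]")

    def pelvic_reference(self, t):
        w = 2.0 * np.pi / self.period
        return self.pelvic_amplitude * np.sin(w * t)

    def pelvic_reference_deriv(self, t):
        w = 2.0 * np.pi / self.period
        return self.pelvic_amplitude * w * np.cos(w * t)

    def pelvic_reference_deriv2(self, t):
        w = 2.0 * np.pi / self.period
        return -self.pelvic_amplitude * w * w * np.sin(w * t)

    def stance_side(self, t: float) -> tuple[str | None, float]:
        """Active side ('right'/'left'/None) and stance progress in [0, 1]."""
        half = 0.5 * self.period
        tm = float(t) % self.period
        h = 0 if tm < half else 1
        local = tm - h * half
        width = self.stance_fraction * half
        start = 0.5 * (half - width)
        if start <= local < start + width:
            side = "right" if h == 0 else "left"
            return side, (local - start) / width
        return None, 0.0


@dataclass(frozen=True)
class GrfProfile:
    """Sine-approximated ground reaction force over one stance.

    Fore-aft: one full sine (braking then propulsion; zero net impulse per
    stance by construction).  Lateral: half sine, always directed toward the
    body midline, so its sign flips with the stance side.
    """

    fore_aft_amplitude: float = 0.1
    lateral_amplitude: float = 0.1

    def __post_init__(self):
        if self.fore_aft_amplitude < 0 or self.lateral_amplitude < 0:
            raise ValueError("GRF amplitudes must be >= 0")


def grf_profile(t: float, schedule: GaitSchedule, profile: GrfProfile):
    """GRF components (f_x, f_y) and the active stance side at time t.

    The model runs toward -x, so braking (first half of stance) acts along
    +x.  Lateral forces point toward the midline: the right foot lies at +y
    (left-handed pair with the -x running direction), so it pushes toward -y.
    """
    side, s = schedule.stance_side(t)
    if side is None:
        return 0.0, 0.0, None
    fx = profile.fore_aft_amplitude * np.sin(2.0 * np.pi * s)
    fy = profile.lateral_amplitude * np.sin(np.pi * s)
    fy = -fy if side == "right" else fy
    return fx, fy, side


@dataclass(frozen=True)
class PdGains:
    kp: float = 0.25
    kd: float = 1.5e-3

    def __post_init__(self):
        if self.kp < 0 or self.kd < 0:
            raise ValueError("PD gains must be >= 0")


def pd_torque(
    desired: tuple[float, float],
    desired_rate: tuple[float, float],
    joint_angles: tuple[float, float],
    joint_rates: tuple[float, float],
    gains: PdGains,
) -> np.ndarray:
    """PD tracking torques (waist, tail) toward the desired joint angles."""
    jd = np.asarray(desired, float)
    jdd = np.asarray(desired_rate, float)
    j = np.asarray(joint_angles, float)
    jr = np.asarray(joint_rates, float)
    return gains.kp * (jd - j) + gains.kd * (jdd - jr)


# --------------------------------------------------------------------------
# state containers


@dataclass
class PlanarState:
    """Full kinematic state; COM positions always satisfy chain closure."""

    time: float
    link_angles: np.ndarray
    link_rates: np.ndarray
    com_positions: np.ndarray  # (3, 2)
    com_velocities: np.ndarray  # (3, 2)

    @property
    def joint_angles(self) -> np.ndarray:
        q = self.link_angles
        return np.array([q[1] - q[0], q[2] - q[1]])

    @property
    def joint_rates(self) -> np.ndarray:
        w = self.link_rates
        return np.array([w[1] - w[0], w[2] - w[1]])


@dataclass
class PlanarForces:
    grf_fore_aft: float = 0.0
    grf_lateral: float = 0.0
    ground_moment: float = 0.0
    joint_torques: np.ndarray = field(default_factory=lambda: np.zeros(2))
    foot_vector: np.ndarray = field(default_factory=lambda: np.zeros(2))


@dataclass
class PlanarTrace:
    """Time series of the planar simulation (all arrays share length nt)."""

    t: np.ndarray
    q: np.ndarray  # (nt, 3) link angles
    qdot: np.ndarray
    com: np.ndarray  # (nt, 2) system COM
    com_vel: np.ndarray
    link_xy: np.ndarray  # (nt, 3, 2)
    joint_angles: np.ndarray  # (nt, 2) waist, tail
    torques: np.ndarray  # (nt, 2) T_bw, T_bt
    grf: np.ndarray  # (nt, 2)
    ground_moment: np.ndarray
    stance_side: np.ndarray  # (nt,) -1 none / 0 right / 1 left
    period: float

    def to_dataframe(self):
        import pandas as pd

        cols = {"t": self.t}
        for i in range(3):
            cols[f"q{i + 1}"] = self.q[:, i]
            cols[f"qd{i + 1}"] = self.qdot[:, i]
        for i in range(3):
            cols[f"x{i + 1}"] = self.link_xy[:, i, 0]
            cols[f"y{i + 1}"] = self.link_xy[:, i, 1]
        cols["com_x"] = self.com[:, 0]
        cols["com_y"] = self.com[:, 1]
        cols["comv_x"] = self.com_vel[:, 0]
        cols["comv_y"] = self.com_vel[:, 1]
        cols["j1"] = self.joint_angles[:, 0]
        cols["j2"] = self.joint_angles[:, 1]
        cols["T_bw"] = self.torques[:, 0]
        cols["T_bt"] = self.torques[:, 1]
        cols["f_x"] = self.grf[:, 0]
        cols["f_y"] = self.grf[:, 1]
        cols["M_z"] = self.ground_moment
        cols["stance_side"] = self.stance_side
        return pd.DataFrame(cols)


_SIDE_CODE = {None: -1, "right": 0, "left": 1}


# --------------------------------------------------------------------------
# simulation


def _initial_state(model, schedule, undulation):
    waist, tail = undulation
    Tp = schedule.period
    q2 = schedule.pelvic_reference(0.0)
    q1 = q2 - waist(0.0, Tp)
    q3 = q2 + tail(0.0, Tp)
    w2 = schedule.pelvic_reference_deriv(0.0)
    w1 = w2 - waist.deriv(0.0, Tp)
    w3 = w2 + tail.deriv(0.0, Tp)
    q = np.array([q1, q2, q3])
    qd = np.array([w1, w2, w3])
    com = np.zeros(2)
    vel = np.array([-schedule.initial_speed, 0.0])
    return np.concatenate([com, vel, q, qd])


def _foot_placement(model, schedule, side, com2):
    """World position of the foot at touchdown, relative to posterior COM.

    The foot is placed ``foot_offset_distance`` from the posterior-body COM
    at ``foot_offset_angle`` off the running direction (-x), laterally on
    the stance side (right = +y, left = -y here).
    """
    d = model.foot_offset_distance
    a = model.foot_offset_angle
    lateral = 1.0 if side == "right" else -1.0
    offset = np.array([-d * np.cos(a), lateral * d * np.sin(a)])
    return com2 + offset


def simulate_stride(
    model: PlanarModel,
    schedule: GaitSchedule,
    grf: GrfProfile,
    gains: PdGains,
    undulation: Sequence[SineParams],
    mz_limit: float | None = None,
    n_periods: int = 1,
    dt: float | None = None,
    grm_tracking_bandwidth: float = 6.0,
) -> PlanarTrace:
    """Fixed-step RK4 simulation of ``n_periods`` gait periods.

    The GRM is realized as the moment required each step for the posterior
    body to track the pelvic reference (a critically damped servo with
    natural frequency ``grm_tracking_bandwidth`` times the gait frequency),
    active only while a foot is in stance and clipped at ``mz_limit`` when
    one is given.
    """
    Tp = schedule.period
    if dt is None:
        dt = Tp / 1000.0
    n_steps = int(round(n_periods * Tp / dt))
    if abs(n_steps * dt - n_periods * Tp) > 1e-9 * Tp:
        raise ValueError("dt must divide the gait period")
    waist, tail = undulation
    wg = grm_tracking_bandwidth * 2.0 * np.pi / Tp
    kp_g, kd_g = wg * wg, 2.0 * wg

    foot_world = {"right": None, "left": None}
    prev_side: str | None = None

    def desired(t):
        jd = np.array([waist(t, Tp), tail(t, Tp)])
        jr = np.array([waist.deriv(t, Tp), tail.deriv(t, Tp)])
        return jd, jr

    def control_and_accel(t, y, side):
        """Torques, GRF, GRM and state derivative at (t, y)."""
        com, vel, q, qd = y[0:2], y[2:4], y[4:7], y[7:10]
        jd, jr = desired(t)
        j = np.array([q[1] - q[0], q[2] - q[1]])
        jrate = np.array([qd[1] - qd[0], qd[2] - qd[1]])
        u = gains.kp * (jd - j) + gains.kd * (jr - jrate)
        fx, fy, _ = grf_profile(t, schedule, grf)
        if side is None:
            fx = fy = 0.0
            p = np.zeros(2)
            mz = 0.0
            qdd = planar_forward_dynamics(model, q, qd, u)
        else:
            offs = com_offsets(model, q)
            com2 = com + offs[1]
            foot = foot_world[side]
            p = foot - com2
            fext_x = np.array([0.0, fx, 0.0])
            fext_y = np.array([0.0, fy, 0.0])
            C, _L = chain_constraint_matrices(model)
            A_eff, rhs_const = _assemble_rotational_system(model, q, qd, fext_x, fext_y)
            tau0 = C.T @ u
            tau0[1] += p[0] * fy - p[1] * fx
            Ainv = np.linalg.inv(A_eff)
            qdd0 = Ainv @ (rhs_const + tau0)
            gain_vec = Ainv[:, 1]
            ref = schedule.pelvic_reference(t)
            refd = schedule.pelvic_reference_deriv(t)
            refdd = schedule.pelvic_reference_deriv2(t)
            qdd2_des = refdd + kp_g * (ref - q[1]) + kd_g * (refd - qd[1])
            mz = (qdd2_des - qdd0[1]) / gain_vec[1]
            if mz_limit is not None:
                mz = float(np.clip(mz, -mz_limit, mz_limit))
            qdd = qdd0 + gain_vec * mz
        acc = np.array([fx, fy]) / model.total_mass
        ydot = np.concatenate([vel, acc, qd, qdd])
        return ydot, u, np.array([fx, fy]), mz, p

    def deriv(t, y, side):
        return control_and_accel(t, y, side)[0]

    y = _initial_state(model, schedule, undulation)
    nt = n_steps + 1
    trace_t = np.linspace(0.0, n_steps * dt, nt)
    Q = np.zeros((nt, 3))
    QD = np.zeros((nt, 3))
    COM = np.zeros((nt, 2))
    CV = np.zeros((nt, 2))
    XY = np.zeros((nt, 3, 2))
    J = np.zeros((nt, 2))
    U = np.zeros((nt, 2))
    F = np.zeros((nt, 2))
    MZ = np.zeros(nt)
    SIDE = np.full(nt, -1)

    for k in range(nt):
        t = trace_t[k]
        side, _ = schedule.stance_side(t)
        if side is not None and side != prev_side:
            com = y[0:2]
            q = y[4:7]
            com2 = com + com_offsets(model, q)[1]
            foot_world[side] = _foot_placement(model, schedule, side, com2)
        prev_side = side

        ydot, u, f, mz, _p = control_and_accel(t, y, side)
        com, q, qd = y[0:2], y[4:7], y[7:10]
        Q[k], QD[k] = q, qd
        COM[k], CV[k] = com, y[2:4]
        XY[k] = com + com_offsets(model, q)
        J[k] = [q[1] - q[0], q[2] - q[1]]
        U[k] = u
        F[k] = f
        MZ[k] = mz
        SIDE[k] = _SIDE_CODE[side]
        if not np.all(np.isfinite(y)):
            raise FloatingPointError(
                f"planar simulation diverged at step {k} (t={t:.6f}); "
                "try a smaller dt"
            )
        if k == n_steps:
            break
        # RK4 step (stance side and foot anchor held over the step)
        k1 = ydot
        k2 = deriv(t + 0.5 * dt, y + 0.5 * dt * k1, side)
        k3 = deriv(t + 0.5 * dt, y + 0.5 * dt * k2, side)
        k4 = deriv(t + dt, y + dt * k3, side)
        y = y + dt / 6.0 * (k1 + 2 * k2 + 2 * k3 + k4)

    return PlanarTrace(
        t=trace_t,
        q=Q,
        qdot=QD,
        com=COM,
        com_vel=CV,
        link_xy=XY,
        joint_angles=J,
        torques=U,
        grf=F,
        ground_moment=MZ,
        stance_side=SIDE,
        period=Tp,
    )
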