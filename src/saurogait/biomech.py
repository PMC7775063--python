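"""15-link, 33-coordinate biomechanical model of a bipedally running lizard.

The trunk (anterior body, posterior body, tail) and four three-segment legs
form a kinematic tree with 30 actuated rotational coordinates plus three
unactuated "virtual" coordinates locating the floating body in the world:
two horizontal translations (q1, q2) and the body yaw (q3).  The body is
held at a constant height above the ground, so the tree is planar-suspended
and all vertical motion comes from the leg joints.

Joint numbering (1-based, as used throughout):

* 1, 2   virtual translations (x, y); 3 body yaw
* 4 waist (z), 5 tail base (z)
* 6-12   left fore leg: shoulder z/x/y, elbow z, wrist z/x/y
* 13-19  right fore leg (mirrored)
* 20-26  left hind leg: hip z/x/y, knee z, ankle z/x/y
* 27-33  right hind leg (mirrored)

All leg motion is prescribed: hind-leg and body joints follow single sines
per stride period, fore-leg joints are frozen at a tucked posture, and the
ankles are servoed so the foot always faces the running direction at a
fixed downward pitch, bending further only to keep the foot end on the
ground during stance.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.optimize import brentq

from .planar import SineParams

__all__ = [
    "BiomechModel",
    "TrajectoryParams",
    "ContactState",
    "GaitTrace",
    "TABLE2_LINKS",
    "build_biomech_model",
    "rot",
    "euler_zxy",
    "forward_kinematics",
    "joint_trajectory",
    "nominal_leg_z",
    "ground_height",
    "ankle_accommodation",
    "stance_windows",
    "step_gait",
    "N_COORDS",
]

N_COORDS = 33

#: Link geometry and mass of the biomechanical model (mm / g).
#: Links 4-9 are the fore legs (upper, lower, hand), 10-15 the hind legs
#: (thigh, shank, foot); paired left/right links share one row each.
TABLE2_LINKS: dict[str, tuple[float, float, float]] = {
    "body1": (66.0, 16.5, 3.6),
    "body2": (42.0, 13.0, 2.9),
    "body3": (84.0, 4.5, 2.0),
    "body4": (16.0, 4.0, 0.11),
    "body5": (12.0, 3.0, 0.06),
    "body6": (15.0, 3.0, 0.03),
    "body7": (16.0, 4.0, 0.11),
    "body8": (12.0, 3.0, 0.06),
    "body9": (15.0, 3.0, 0.03),
    "body10": (19.0, 7.5, 0.36),
    "body11": (21.0, 4.5, 0.18),
    "body12": (13.0, 3.5, 0.08),
    "body13": (19.0, 7.5, 0.36),
    "body14": (21.0, 4.5, 0.18),
    "body15": (13.0, 3.5, 0.08),
}

_AXIS_INDEX = {"x": 0, "y": 1, "z": 2}


def rot(axis: str, angle: float) -> np.ndarray:
    """Right-handed elementary rotation matrix about a world-aligned axis."""
    c, s = np.cos(angle), np.sin(angle)
    if axis == "x":
        return np.array([[1, 0, 0], [0, c, -s], [0, s, c]])
    if axis == "y":
        return np.array([[c, 0, s], [0, 1, 0], [-s, 0, c]])
    if axis == "z":
        return np.array([[c, -s, 0], [s, c, 0], [0, 0, 1]])
    raise ValueError(f"unknown axis {axis!r}")


def euler_zxy(R: np.ndarray) -> tuple[float, float, float]:
    """Angles (a, b, c) with R = Rot(a, z) Rot(b, x) Rot(c, y)."""
    b = float(np.arcsin(np.clip(R[2, 1], -1.0, 1.0)))
    c = float(np.arctan2(-R[2, 0], R[2, 2]))
    a = float(np.arctan2(-R[0, 1], R[1, 1]))
    return a, b, c


@dataclass
class TreeStructure:
    """Precomputed tree wiring shared by kinematics and dynamics."""

    joints: list
    bodies: list
    inertias: list
    ancestors: list


@dataclass(frozen=True)
class BiomechModel:
    """Geometry and mass of the 15-link tree (SI units)."""

    link_lengths: np.ndarray  # (15,)
    link_widths: np.ndarray
    link_masses: np.ndarray
    shoulder_x: float
    shoulder_y: float
    pelvic_x: float
    pelvic_y: float
    foot_pitch: float = np.deg2rad(15.0)  # fixed downward pitch of the foot

    def __post_init__(self):
        for name in ("link_lengths", "link_widths", "link_masses"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != (15,):
                raise ValueError(f"{name} must have shape (15,)")
            if np.any(arr <= 0):
                raise ValueError(f"{name} entries must be strictly positive")
            object.__setattr__(self, name, arr)

    @property
    def total_mass(self) -> float:
        return float(self.link_masses.sum())

    # ---- tree structure -------------------------------------------------
    # joints: (parent 1-based or 0 for world, kind 'r'/'p', axis,
    #          translation from parent joint origin, in the parent frame)
    def joint_table(self):
        l = self.link_lengths
        sx, sy = self.shoulder_x, self.shoulder_y
        px, py = self.pelvic_x, self.pelvic_y
        z3 = np.zeros(3)

        def t(x, y=0.0, z=0.0):
            return np.array([x, y, z])

        joints = [None] * (N_COORDS + 1)
        joints[1] = (0, "p", "x", z3)
        joints[2] = (1, "p", "y", z3)
        joints[3] = (2, "r", "z", z3)
        joints[4] = (3, "r", "z", t(l[0]))
        joints[5] = (4, "r", "z", t(l[1]))
        # left fore (shoulder at body1 COM + (sx, -sy))
        joints[6] = (3, "r", "z", t(l[0] / 2 + sx, -sy))
        joints[7] = (6, "r", "x", z3)
        joints[8] = (7, "r", "y", z3)
        joints[9] = (8, "r", "z", t(0.0, -l[3]))
        joints[10] = (9, "r", "z", t(-l[4]))
        joints[11] = (10, "r", "x", z3)
        joints[12] = (11, "r", "y", z3)
        # right fore
        joints[13] = (3, "r", "z", t(l[0] / 2 + sx, sy))
        joints[14] = (13, "r", "x", z3)
        joints[15] = (14, "r", "y", z3)
        joints[16] = (15, "r", "z", t(0.0, l[6]))
        joints[17] = (16, "r", "z", t(-l[7]))
        joints[18] = (17, "r", "x", z3)
        joints[19] = (18, "r", "y", z3)
        # left hind (hip at body2 COM + (px, -py))
        joints[20] = (4, "r", "z", t(l[1] / 2 + px, -py))
        joints[21] = (20, "r", "x", z3)
        joints[22] = (21, "r", "y", z3)
        joints[23] = (22, "r", "z", t(0.0, -l[9]))
        joints[24] = (23, "r", "z", t(l[10]))
        joints[25] = (24, "r", "x", z3)
        joints[26] = (25, "r", "y", z3)
        # right hind
        joints[27] = (4, "r", "z", t(l[1] / 2 + px, py))
        joints[28] = (27, "r", "x", z3)
        joints[29] = (28, "r", "y", z3)
        joints[30] = (29, "r", "z", t(0.0, l[12]))
        joints[31] = (30, "r", "z", t(l[13]))
        joints[32] = (31, "r", "x", z3)
        joints[33] = (32, "r", "y", z3)
        return joints

    # bodies: (supporting joint 1-based, COM offset in that frame, long axis)
    def body_table(self):
        l = self.link_lengths

        def t(x, y=0.0, z=0.0):
            return np.array([x, y, z])

        return [
            (3, t(l[0] / 2), "x"),
            (4, t(l[1] / 2), "x"),
            (5, t(l[2] / 2), "x"),
            (8, t(0.0, -l[3] / 2), "y"),
            (9, t(-l[4] / 2), "x"),
            (12, t(-l[5] / 2), "x"),
            (15, t(0.0, l[6] / 2), "y"),
            (16, t(-l[7] / 2), "x"),
            (19, t(-l[8] / 2), "x"),
            (22, t(0.0, -l[9] / 2), "y"),
            (23, t(l[10] / 2), "x"),
            (26, t(l[11] / 2), "x"),
            (29, t(0.0, l[12] / 2), "y"),
            (30, t(l[13] / 2), "x"),
            (33, t(l[14] / 2), "x"),
        ]

    def body_inertia(self, i: int) -> np.ndarray:
        """Body-frame inertia tensor of link i (0-based), cylinder rule."""
        return self.structure().inertias[i]

    def structure(self) -> "TreeStructure":
        """Cached joint/body tables, inertia tensors and ancestor lists."""
        cached = self.__dict__.get("_structure")
        if cached is None:
            joints = self.joint_table()
            bodies = self.body_table()
            inertias = []
            for i, (_jb, _off, axis) in enumerate(bodies):
                m = self.link_masses[i]
                l = self.link_lengths[i]
                r = 0.5 * self.link_widths[i]
                trans = m * (l * l / 12.0 + r * r / 4.0)
                longit = 0.5 * m * r * r
                diag = np.full(3, trans)
                diag[_AXIS_INDEX[axis]] = longit
                inertias.append(np.diag(diag))
            ancestors = [None] * (N_COORDS + 1)
            for j in range(1, N_COORDS + 1):
                parent = joints[j][0]
                ancestors[j] = ([] if parent == 0 else list(ancestors[parent])) + [j]
            cached = TreeStructure(joints, bodies, inertias, ancestors)
            object.__setattr__(self, "_structure", cached)
        return cached


def build_biomech_model(
    table2: Mapping[str, Sequence[float]] | None = None,
    *,
    shoulder_x_mm: float | None = None,
    shoulder_y_mm: float | None = None,
    pelvic_x_mm: float | None = None,
    pelvic_y_mm: float | None = None,
    foot_pitch_deg: float = 15.0,
) -> BiomechModel:
    """Build a :class:`BiomechModel` from a link table in mm/g.

    ``table2`` maps link names ``body1`` .. ``body15`` to
    (length_mm, width_mm, mass_g).  Shoulder/pelvic attachment offsets
    default to the front of body1 / rear of body2 with lateral offsets of
    half the respective body width.
    """
    table = dict(TABLE2_LINKS if table2 is None else table2)
    rows = []
    for i in range(1, 16):
        key = f"body{i}"
        if key not in table:
            raise ValueError(f"missing link entry: {key}")
        row = [float(v) for v in table[key]]
        if len(row) != 3 or any(v <= 0 for v in row):
            raise ValueError(f"link {key} must have 3 positive values (mm, mm, g)")
        rows.append(row)
    arr = np.array(rows)
    lengths = arr[:, 0] * 1e-3
    widths = arr[:, 1] * 1e-3
    masses = arr[:, 2] * 1e-3
    sx = -lengths[0] / 2 if shoulder_x_mm is None else shoulder_x_mm * 1e-3
    sy = widths[0] / 2 if shoulder_y_mm is None else shoulder_y_mm * 1e-3
    px = lengths[1] / 2 if pelvic_x_mm is None else pelvic_x_mm * 1e-3
    py = widths[1] / 2 if pelvic_y_mm is None else pelvic_y_mm * 1e-3
    return BiomechModel(
        link_lengths=lengths,
        link_widths=widths,
        link_masses=masses,
        shoulder_x=sx,
        shoulder_y=sy,
        pelvic_x=px,
        pelvic_y=py,
        foot_pitch=np.deg2rad(foot_pitch_deg),
    )


# --------------------------------------------------------------------------
# forward kinematics


@dataclass
class FkResult:
    """World pose of every joint frame plus link COM and landmark positions."""

    origins: np.ndarray  # (34, 3), entry 0 = world, i = joint i origin
    rotations: np.ndarray  # (34, 3, 3) world orientation after joint i
    axes: np.ndarray  # (34, 3) world direction of joint i's axis
    com: np.ndarray  # (15, 3) link COM positions
    landmarks: dict[str, np.ndarray]


def forward_kinematics(model: BiomechModel, q: np.ndarray) -> FkResult:
    """Pose of every frame of the tree for joint vector q (length 33)."""
    q = np.asarray(q, float)
    if q.shape != (N_COORDS,):
        raise ValueError("q must have length 33")
    joints = model.structure().joints
    origins = np.zeros((N_COORDS + 1, 3))
    rotations = np.zeros((N_COORDS + 1, 3, 3))
    axes = np.zeros((N_COORDS + 1, 3))
    rotations[0] = np.eye(3)
    unit = {a: np.eye(3)[i] for a, i in _AXIS_INDEX.items()}
    for j in range(1, N_COORDS + 1):
        parent, kind, axis, trans = joints[j]
        Rp = rotations[parent]
        op = origins[parent] + Rp @ trans
        w = Rp @ unit[axis]
        if kind == "p":
            origins[j] = op + w * q[j - 1]
            rotations[j] = Rp
        else:
            origins[j] = op
            rotations[j] = Rp @ rot(axis, q[j - 1])
        axes[j] = w
    com = np.zeros((15, 3))
    for i, (joint, offset, _axis) in enumerate(model.structure().bodies):
        com[i] = origins[joint] + rotations[joint] @ offset
    l = model.link_lengths
    landmarks = {
        "hip_left": origins[20],
        "hip_right": origins[27],
        "knee_left": origins[23],
        "knee_right": origins[30],
        "ankle_left": origins[24],
        "ankle_right": origins[31],
        "tiptoe_left": origins[26] + rotations[26] @ np.array([l[11], 0, 0]),
        "tiptoe_right": origins[33] + rotations[33] @ np.array([l[14], 0, 0]),
        "snout": origins[3],
        "tail_tip": origins[5] + rotations[5] @ np.array([l[2], 0, 0]),
    }
    return FkResult(origins, rotations, axes, com, landmarks)


# --------------------------------------------------------------------------
# prescribed joint trajectories


@dataclass(frozen=True)
class TrajectoryParams:
    """Sine parameters of the prescribed gait.

    The virtual yaw q3 carries the prescribed pelvic-rotation sine
    ``yaw_offset + pelvic_amplitude * sin(2 pi t / period)``; the pelvis
    itself swings as the sum of this sine and the waist joint, so larger
    waist amplitudes sweep the hips further and lengthen the stride (the
    default waist phase pi keeps the pelvic swing near the reference
    amplitude while the trunk bends into the alternating S).  Left hind-leg
    joints carry explicit sines; the right leg repeats them half a period
    later, mirrored (z- and x-rotations and the knee negated via the sign
    rules of the printed mirror table; the shoulder-y sine phase-shifted by
    pi).  Fore-leg joints are constants.
    """

    period: float = 0.03
    pelvic_amplitude: float = np.deg2rad(20.0)
    yaw_offset: float = np.pi  # so the snout leads in +x
    waist: SineParams = field(default_factory=lambda: SineParams(np.deg2rad(40.0), np.pi))
    tail: SineParams = field(default_factory=lambda: SineParams(np.deg2rad(40.0), 0.0))
    # default leg gait: sprawled-runner pattern — propulsion from a large
    # horizontal limb sweep, small vertical clearance of the recovery foot
    hip_swing: SineParams = field(  # q20, about z: pro-/retraction
        default_factory=lambda: SineParams(np.deg2rad(45.0), -np.pi / 2, 0.0)
    )
    hip_lift: SineParams = field(  # q21, about x: thigh depression
        default_factory=lambda: SineParams(np.deg2rad(10.0), 0.0, np.deg2rad(40.0))
    )
    hip_roll: SineParams = field(  # q22, about y: femoral long-axis rotation
        default_factory=lambda: SineParams(np.deg2rad(15.0), 0.0, 0.0)
    )
    knee: SineParams = field(  # q23, about z
        default_factory=lambda: SineParams(np.deg2rad(30.0), -np.pi / 2, np.deg2rad(-35.0))
    )
    foreleg_constants: tuple[float, ...] = (
        np.deg2rad(-30.0), np.deg2rad(40.0), 0.0,  # left shoulder z, x, y
        np.deg2rad(60.0),                          # left elbow
        0.0, 0.0, 0.0,                             # left wrist z, x, y
    )

    def __post_init__(self):
        if self.period <= 0:
            raise ValueError("period must be positive")
        if len(self.foreleg_constants) != 7:
            raise ValueError("foreleg_constants must give the 7 left-side joints")

    def pelvic(self, t):
        return self.pelvic_amplitude * np.sin(2.0 * np.pi * t / self.period)

    # ---- per-joint sine table (joints 4, 5, 20..23 left, 27..30 right) --
    def left_sines(self) -> dict[int, SineParams]:
        return {4: self.waist, 5: self.tail, 20: self.hip_swing,
                21: self.hip_lift, 22: self.hip_roll, 23: self.knee}

    def right_sines(self) -> dict[int, SineParams]:
        """Right hind-leg sines from the printed mirror rules.

        z/x rotations and the knee: ``a sin(wt + b) - c`` (equal to the
        negated left joint half a period later); shoulder-y:
        ``a sin(wt + b + pi) - c``.
        """
        out = {}
        for j_left, j_right in ((20, 27), (21, 28), (23, 30)):
            p = self.left_sines()[j_left]
            out[j_right] = SineParams(p.amplitude, p.phase, -p.offset)
        p = self.hip_roll
        out[29] = SineParams(p.amplitude, p.phase + np.pi, -p.offset)
        return out


def _sine_joints(params: TrajectoryParams):
    """Joint -> SineParams for every sine-driven coordinate (1-based)."""
    table = dict(params.left_sines())
    table.update(params.right_sines())
    return table


def joint_trajectory(t: float, params: TrajectoryParams, model: BiomechModel | None = None):
    """Prescribed joint vector q (and analytic q̇, q̈) at time t.

    Virtual translations q1, q2 are left at zero (the gait stepper fills
    them in); q3 follows the pelvic-yaw constraint.  If a model is given,
    the ankle coordinates are set to the forward-facing foot posture
    (world-frame yaw 0, roll 0, pitch ``model.foot_pitch``); their rates are
    not analytic and are returned as zero.
    """
    Tp = params.period
    q = np.zeros(N_COORDS)
    qd = np.zeros(N_COORDS)
    qdd = np.zeros(N_COORDS)
    for j, p in _sine_joints(params).items():
        q[j - 1] = p(t, Tp)
        qd[j - 1] = p.deriv(t, Tp)
        qdd[j - 1] = p.deriv2(t, Tp)
    # fore-leg constants: left 6..12, right mirrored (z/x negated, y kept)
    fl = params.foreleg_constants
    q[5:12] = fl
    mirror_sign = np.array([-1, -1, 1, -1, -1, -1, 1], dtype=float)
    q[12:19] = mirror_sign * np.asarray(fl)
    # virtual yaw carries the prescribed pelvic-rotation sine
    w = 2.0 * np.pi / Tp
    q[2] = params.yaw_offset + params.pelvic(t)
    qd[2] = params.pelvic_amplitude * w * np.cos(w * t)
    qdd[2] = -params.pelvic_amplitude * w * w * np.sin(w * t)
    if model is not None:
        for side in ("left", "right"):
            a, b, c = nominal_ankle_angles(model, q, side)
            base = 23 if side == "left" else 30
            q[base], q[base + 1], q[base + 2] = a, b, c
    return q, qd, qdd


def _ankle_parent_rotation(model: BiomechModel, q: np.ndarray, side: str) -> np.ndarray:
    """World orientation of the frame the ankle joints rotate in."""
    if side == "left":
        idx = [3, 4, 20, 21, 22, 23]
        axes = "zzzxyz"
    else:
        idx = [3, 4, 27, 28, 29, 30]
        axes = "zzzxyz"
    R = np.eye(3)
    for j, ax in zip(idx, axes):
        R = R @ rot(ax, q[j - 1])
    return R


def nominal_ankle_angles(model: BiomechModel, q: np.ndarray, side: str):
    """Ankle (z, x, y) angles making the foot face forward at the set pitch."""
    Rp = _ankle_parent_rotation(model, q, side)
    return euler_zxy(Rp.T @ rot("y", model.foot_pitch))


def nominal_leg_z(model: BiomechModel, params: TrajectoryParams, t, side: str = "left"):
    """Ankle, foot-center and tiptoe heights of the swing trajectory at t.

    All heights are closed-form in the hip x/y and knee angles: yaw (z)
    rotations anywhere in the chain do not move material out of the plane,
    so only the hip depression, femoral rotation and knee flexion enter.
    With the foot in its forward-facing posture the foot segment is pitched
    down by ``foot_pitch``, so the center and tip sit below the ankle by
    half resp. one foot length times sin(pitch).
    """
    tarr = np.atleast_1d(np.asarray(t, float))
    Tp = params.period
    if side == "left":
        sines = params.left_sines()
        qx = sines[21](tarr, Tp)
        qy = sines[22](tarr, Tp)
        qk = sines[23](tarr, Tp)
        l_thigh, l_shank, lf = model.link_lengths[9:12]
        thigh_sign = -1.0
    else:
        sines = params.right_sines()
        qx = sines[28](tarr, Tp)
        qy = sines[29](tarr, Tp)
        qk = sines[30](tarr, Tp)
        l_thigh, l_shank, lf = model.link_lengths[12:15]
        thigh_sign = 1.0
    ankle = thigh_sign * l_thigh * np.sin(qx) + l_shank * (
        np.sin(qx) * np.sin(qk) - np.cos(qx) * np.sin(qy) * np.cos(qk)
    )
    drop = np.sin(model.foot_pitch)
    center = ankle - 0.5 * lf * drop
    tip = ankle - lf * drop
    if np.isscalar(t) or np.ndim(t) == 0:
        return ankle[0], center[0], tip[0]
    return ankle, center, tip


def ground_height(model: BiomechModel, params: TrajectoryParams, n_samples: int = 1200) -> float:
    """Ground plane height z_g below the constant-height body.

    The ground is placed at the minimum over one cycle of the swing foot's
    center height, which lies between the minimum tiptoe and minimum ankle
    heights, so the foot end dips below the ground (triggering stance and
    ankle accommodation) while the ankle never does.
    """
    if min(model.link_lengths[9:12]) <= 0:
        raise ValueError("degenerate hind leg")
    ts = np.linspace(0.0, params.period, n_samples, endpoint=False)
    _, center, _ = nominal_leg_z(model, params, ts)
    return float(center.min())


def ankle_accommodation(
    model: BiomechModel, q: np.ndarray, z_g: float, side: str = "left"
) -> np.ndarray:
    """Bend the ankle pitch so the foot end sits exactly on the ground.

    Keeps the nominal ankle z- and x-rotations and solves the y-rotation in
    closed form from ``tip_z(gamma) = z_g`` (choosing the solution nearest
    the nominal pitch).  If the nominal foot end is at or above the ground
    the posture is returned unchanged; an unreachable ground raises.
    """
    q = np.asarray(q, float).copy()
    base = 23 if side == "left" else 30
    lf = model.link_lengths[11] if side == "left" else model.link_lengths[14]
    fk = forward_kinematics(model, q)
    tip_z = fk.landmarks[f"tiptoe_{side}"][2]
    if tip_z >= z_g - 1e-12:
        return q
    ankle_z = fk.landmarks[f"ankle_{side}"][2]
    Rp = _ankle_parent_rotation(model, q, side)
    M = Rp @ rot("z", q[base]) @ rot("x", q[base + 1])
    a, b = M[2, 0], M[2, 2]
    c = (z_g - ankle_z) / lf
    r = np.hypot(a, b)
    if abs(c) > r:
        raise ValueError("ground is unreachable from the ankle at this pose")
    delta = np.arctan2(b, a)
    acos = np.arccos(np.clip(c / r, -1.0, 1.0))
    gamma_nominal = q[base + 2]
    candidates = []
    for sign in (1.0, -1.0):
        g = sign * acos - delta
        g = (g - gamma_nominal + np.pi) % (2 * np.pi) - np.pi + gamma_nominal
        candidates.append(g)
    q[base + 2] = min(candidates, key=lambda g: abs(g - gamma_nominal))
    return q


# --------------------------------------------------------------------------
# gait stepping


@dataclass
class ContactState:
    side: str | None = None
    anchor: np.ndarray | None = None  # fixed tiptoe world position
    touchdown_time: float | None = None
    liftoff_time: float | None = None
    ground_height: float = 0.0


def stance_windows(model: BiomechModel, params: TrajectoryParams, z_g: float,
                   n_scan: int = 800):
    """Per-foot stance intervals within one period, [(t_on, t_off), ...].

    A foot is in stance while its nominal (forward-facing) tiptoe height is
    below the ground plane; boundaries are refined by root finding on the
    periodic tiptoe-height function.
    """
    Tp = params.period
    out = {}
    for side in ("left", "right"):
        def depth(t):
            _, _, tip = nominal_leg_z(model, params, float(t % Tp), side)
            return tip - z_g

        ts = np.linspace(0.0, Tp, n_scan, endpoint=False)
        vals = np.array([depth(t) for t in ts])
        below = vals < 0
        if not below.any():
            out[side] = []
            continue
        # find rising/falling edges on the periodic grid
        edges = np.flatnonzero(np.diff(below.astype(int), append=below[0].astype(int)))
        windows = []
        starts = [k for k in edges if not below[k]]
        for k in starts:
            t_on = brentq(depth, ts[k], ts[k] + Tp / n_scan, xtol=1e-12)
            # walk forward to the matching falling edge
            k2 = k
            while True:
                k2 = (k2 + 1) % n_scan
                if not below[k2]:
                    break
            t_off_lo = ts[k2 - 1] if k2 > 0 else ts[-1]
            t_off = brentq(depth, t_off_lo, t_off_lo + Tp / n_scan, xtol=1e-12)
            if t_off < t_on:
                t_off += Tp
            windows.append((t_on, t_off))
        out[side] = sorted(windows)
    return out


@dataclass
class GaitTrace:
    """Time series of the biomechanical gait."""

    t: np.ndarray
    q: np.ndarray  # (nt, 33)
    contact: np.ndarray  # (nt,) -1 aerial / 0 left / 1 right
    tiptoe_left: np.ndarray  # (nt, 3)
    tiptoe_right: np.ndarray
    hip_left: np.ndarray
    hip_right: np.ndarray
    com: np.ndarray  # (nt, 3)
    ground_height: float
    period: float
    touchdowns: list  # (time, side, world xy of the anchor)
    model: BiomechModel | None = None
    params: TrajectoryParams | None = None

    @property
    def dt(self) -> float:
        return float(self.t[1] - self.t[0])

    def to_dataframe(self):
        import pandas as pd

        cols = {"t": self.t}
        for i in range(N_COORDS):
            cols[f"q{i + 1}"] = self.q[:, i]
        cols["contact"] = self.contact
        for name, arr in (
            ("tiptoe_left", self.tiptoe_left),
            ("tiptoe_right", self.tiptoe_right),
            ("hip_left", self.hip_left),
            ("hip_right", self.hip_right),
            ("com", self.com),
        ):
            for k, ax in enumerate("xyz"):
                cols[f"{name}_{ax}"] = arr[:, k]
        return pd.DataFrame(cols)


_CONTACT_CODE = {None: -1, "left": 0, "right": 1}


def step_gait(
    model: BiomechModel,
    params: TrajectoryParams,
    n_strides: int = 4,
    steps_per_period: int = 300,
    initial_speed: float = 4.0,
    z_g: float | None = None,
    double_stance: str = "warn",
) -> GaitTrace:
    """March the prescribed gait through ``n_strides`` periods.

    While a foot is in stance its tiptoe is pinned to the world point where
    it touched down, and the virtual translations are solved (linearly, as
    they are pure world translations) so the chain passes through it; during
    aerial phases the model's COM translates at its liftoff velocity.  The
    body never leaves the constant-height plane.
    """
    Tp = params.period
    dt = Tp / steps_per_period
    if z_g is None:
        z_g = ground_height(model, params)
    windows = stance_windows(model, params, z_g)

    def active_side(t):  # noqa: C901 - small state machine
        return _active_side(t, Tp, windows, double_stance)

    nt = n_strides * steps_per_period + 1
    ts = np.arange(nt) * dt

    # --- batched posture over the whole grid ---------------------------
    Q = _nominal_joint_trace(model, params, ts)
    Q = _accommodate_trace(model, params, Q, z_g)
    from ._batch import batch_fk

    origins, rotations, _axes = batch_fk(model, Q)
    struct = model.structure()
    masses = model.link_masses
    com0 = np.zeros((nt, 3))
    for i, (jb, offset, _ax) in enumerate(struct.bodies):
        com0 += masses[i] * (origins[:, jb] + rotations[:, jb] @ offset)
    com0 /= masses.sum()
    lf_l, lf_r = model.link_lengths[11], model.link_lengths[14]
    tip0 = {
        "left": origins[:, 26] + rotations[:, 26] @ np.array([lf_l, 0.0, 0.0]),
        "right": origins[:, 33] + rotations[:, 33] @ np.array([lf_r, 0.0, 0.0]),
    }
    hip0 = {"left": origins[:, 20], "right": origins[:, 27]}

    CONTACT = np.full(nt, -1)
    BASE = np.zeros((nt, 2))
    touchdowns = []
    state = ContactState(ground_height=z_g)
    com_vel = np.array([initial_speed, 0.0])
    com_ref_xy = None
    com_ref_t = 0.0
    prev_side = None
    COMW = np.zeros((nt, 2))

    for k, t in enumerate(ts):
        side = active_side(t)
        if side is None:
            if prev_side is not None and k >= 2:
                rel = (com0[:, :2] - tip0[prev_side][:, :2])
                com_vel = (rel[k - 1] - rel[k - 2]) / dt
                com_ref_xy = COMW[k - 1] + com_vel * dt
                com_ref_t = t
                state = ContactState(ground_height=z_g)
            if com_ref_xy is None:
                com_ref_xy = com0[k, :2]
                com_ref_t = t
            com_target = com_ref_xy + com_vel * (t - com_ref_t)
            base_xy = com_target - com0[k, :2]
        else:
            if side != prev_side:
                if com_ref_xy is None:
                    com_ref_t = t
                    if k >= 2:
                        v_est = (COMW[k - 1] - COMW[k - 2]) / dt
                        com_ref_xy = COMW[k - 1] + v_est * dt
                    elif k == 1:
                        com_ref_xy = COMW[0] + com_vel * dt
                    else:
                        com_ref_xy = com0[0, :2]
                com_target = com_ref_xy + com_vel * (t - com_ref_t)
                anchor = tip0[side][k, :2] + (com_target - com0[k, :2])
                state = ContactState(
                    side=side, anchor=anchor, touchdown_time=t, ground_height=z_g
                )
                touchdowns.append((t, side, anchor.copy()))
            base_xy = state.anchor - tip0[side][k, :2]
            com_ref_xy = None
        prev_side = side
        BASE[k] = base_xy
        COMW[k] = com0[k, :2] + base_xy
        CONTACT[k] = _CONTACT_CODE[side]

    Q[:, 0] = BASE[:, 0]
    Q[:, 1] = BASE[:, 1]
    shift = np.concatenate([BASE, np.zeros((nt, 1))], axis=1)
    return GaitTrace(
        t=ts,
        q=Q,
        contact=CONTACT,
        tiptoe_left=tip0["left"] + shift,
        tiptoe_right=tip0["right"] + shift,
        hip_left=hip0["left"] + shift,
        hip_right=hip0["right"] + shift,
        com=com0 + shift,
        ground_height=z_g,
        period=Tp,
        touchdowns=touchdowns,
        model=model,
        params=params,
    )


def _active_side(t, Tp, windows, double_stance):
    """Stance side at time t from the per-foot periodic windows."""
    tm = t % Tp
    hits = []
    for side, wins in windows.items():
        for t_on, t_off in wins:
            if t_on <= tm < t_off or t_on <= tm + Tp < t_off:
                hits.append((side, t_on))
    if not hits:
        return None
    if len(hits) > 1:
        if double_stance == "error":
            raise RuntimeError(f"double stance at t={t:.5f}")
        if double_stance == "warn":
            import warnings

            warnings.warn("double stance detected; keeping the earlier touchdown")
        hits.sort(key=lambda h: h[1])
    return hits[0][0]


def _nominal_joint_trace(model: BiomechModel, params: TrajectoryParams,
                         ts: np.ndarray) -> np.ndarray:
    """(nt, 33) joint trace with nominal forward-facing ankles, q1 = q2 = 0."""
    from ._batch import batch_fk

    ts = np.asarray(ts, float)
    nt = ts.shape[0]
    Tp = params.period
    Q = np.zeros((nt, N_COORDS))
    for j, p in _sine_joints(params).items():
        Q[:, j - 1] = p(ts, Tp)
    fl = np.asarray(params.foreleg_constants)
    mirror_sign = np.array([-1, -1, 1, -1, -1, -1, 1], dtype=float)
    Q[:, 5:12] = fl
    Q[:, 12:19] = mirror_sign * fl
    Q[:, 2] = params.yaw_offset + params.pelvic(ts)
    # forward-facing ankles: decompose R_parent^T Ry(pitch) as z-x-y angles
    _o, rotations, _a = batch_fk(model, Q)
    target = rot("y", model.foot_pitch)
    for knee_joint, col in ((23, 23), (30, 30)):
        R = np.swapaxes(rotations[:, knee_joint], 1, 2) @ target
        # unwrap the atan2 angles so differencing the trace stays meaningful
        Q[:, col] = np.unwrap(np.arctan2(-R[:, 0, 1], R[:, 1, 1]))
        Q[:, col + 1] = np.arcsin(np.clip(R[:, 2, 1], -1.0, 1.0))
        Q[:, col + 2] = np.unwrap(np.arctan2(-R[:, 2, 0], R[:, 2, 2]))
    return Q


def _accommodate_trace(model: BiomechModel, params: TrajectoryParams,
                       Q: np.ndarray, z_g: float) -> np.ndarray:
    """Bend stance ankles so foot ends sit on the ground, over a whole trace."""
    from ._batch import batch_fk

    Q = Q.copy()
    origins, rotations, _a = batch_fk(model, Q)
    for side, col, ankle_joint, lf in (
        ("left", 23, 24, model.link_lengths[11]),
        ("right", 30, 31, model.link_lengths[14]),
    ):
        ankle_z = origins[:, ankle_joint, 2]
        tip_z = ankle_z - lf * np.sin(model.foot_pitch)
        mask = tip_z < z_g - 1e-12
        if not mask.any():
            continue
        knee_joint = ankle_joint - 1
        Rpre = rotations[mask, knee_joint]
        M = (
            Rpre
            @ _rot_batch_local("z", Q[mask, col])
            @ _rot_batch_local("x", Q[mask, col + 1])
        )
        a, b = M[:, 2, 0], M[:, 2, 2]
        c = (z_g - ankle_z[mask]) / lf
        r = np.hypot(a, b)
        if np.any(np.abs(c) > r):
            raise ValueError("ground is unreachable from the ankle at some pose")
        delta = np.arctan2(b, a)
        acos = np.arccos(np.clip(c / r, -1.0, 1.0))
        gnom = Q[mask, col + 2]
        best = None
        for sign in (1.0, -1.0):
            g = sign * acos - delta
            g = (g - gnom + np.pi) % (2 * np.pi) - np.pi + gnom
            best = g if best is None else np.where(
                np.abs(g - gnom) < np.abs(best - gnom), g, best
            )
        Q[mask, col + 2] = best
    return Q


def _rot_batch_local(axis: str, angles: np.ndarray) -> np.ndarray:
    from ._batch import _rot_batch

    return _rot_batch(axis, np.asarray(angles, float))
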