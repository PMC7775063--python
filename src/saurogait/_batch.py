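"""Time-batched kinematics and dynamics used by the gait-analysis pipeline.

Same algorithms as :mod:`saurogait.dynamics` (verified against them in the
test suite), vectorized over the trace's time axis so per-call numpy
overhead amortizes across samples.
"""

from __future__ import annotations

import numpy as np

from .biomech import N_COORDS, BiomechModel

__all__ = ["batch_fk", "batch_rnea", "batch_mass_matrix", "batch_contact_jacobian"]

_AXIS = {"x": 0, "y": 1, "z": 2}


def _rot_batch(axis: str, angles: np.ndarray) -> np.ndarray:
    nt = angles.shape[0]
    c, s = np.cos(angles), np.sin(angles)
    R = np.zeros((nt, 3, 3))
    if axis == "x":
        R[:, 0, 0] = 1.0
        R[:, 1, 1] = c
        R[:, 1, 2] = -s
        R[:, 2, 1] = s
        R[:, 2, 2] = c
    elif axis == "y":
        R[:, 1, 1] = 1.0
        R[:, 0, 0] = c
        R[:, 0, 2] = s
        R[:, 2, 0] = -s
        R[:, 2, 2] = c
    else:
        R[:, 2, 2] = 1.0
        R[:, 0, 0] = c
        R[:, 0, 1] = -s
        R[:, 1, 0] = s
        R[:, 1, 1] = c
    return R


def batch_fk(model: BiomechModel, Q: np.ndarray):
    """World frames for a (nt, 33) joint trace.

    Returns (origins (nt,34,3), rotations (nt,34,3,3), axes (nt,34,3)).
    """
    Q = np.asarray(Q, float)
    nt = Q.shape[0]
    joints = model.structure().joints
    origins = np.zeros((nt, N_COORDS + 1, 3))
    rotations = np.zeros((nt, N_COORDS + 1, 3, 3))
    axes = np.zeros((nt, N_COORDS + 1, 3))
    rotations[:, 0] = np.eye(3)
    eye = np.eye(3)
    for j in range(1, N_COORDS + 1):
        parent, kind, axis, trans = joints[j]
        Rp = rotations[:, parent]
        s = Rp[:, :, _AXIS[axis]]
        axes[:, j] = s
        base = origins[:, parent] + Rp @ trans
        if kind == "p":
            origins[:, j] = base + s * Q[:, j - 1][:, None]
            rotations[:, j] = Rp
        else:
            origins[:, j] = base
            rotations[:, j] = Rp @ _rot_batch(axis, Q[:, j - 1])
    return origins, rotations, axes


def batch_rnea(model, Q, QD, QDD, gravity=9.81):
    """Recursive Newton-Euler over a whole trace: (nt, 33) torques."""
    Q, QD, QDD = (np.asarray(x, float) for x in (Q, QD, QDD))
    nt = Q.shape[0]
    struct = model.structure()
    joints = struct.joints
    gvec = np.array([0.0, 0.0, -gravity]) if np.isscalar(gravity) else (
        np.zeros(3) if gravity is None else np.asarray(gravity, float)
    )
    n = N_COORDS
    R = np.zeros((nt, n + 1, 3, 3))
    o = np.zeros((nt, n + 1, 3))
    w = np.zeros((nt, n + 1, 3))
    al = np.zeros((nt, n + 1, 3))
    a = np.zeros((nt, n + 1, 3))
    s_ax = np.zeros((nt, n + 1, 3))
    R[:, 0] = np.eye(3)
    for j in range(1, n + 1):
        parent, kind, axis, trans = joints[j]
        Rp = R[:, parent]
        s = Rp[:, :, _AXIS[axis]]
        s_ax[:, j] = s
        qj = Q[:, j - 1][:, None]
        qdj = QD[:, j - 1][:, None]
        qddj = QDD[:, j - 1][:, None]
        if kind == "p":
            d = Rp @ trans + s * qj
            o[:, j] = o[:, parent] + d
            R[:, j] = Rp
            w[:, j] = w[:, parent]
            al[:, j] = al[:, parent]
            a[:, j] = (
                a[:, parent]
                + np.cross(al[:, parent], d)
                + np.cross(w[:, parent], np.cross(w[:, parent], d))
                + 2.0 * np.cross(w[:, parent], s * qdj)
                + s * qddj
            )
        else:
            d = Rp @ trans
            o[:, j] = o[:, parent] + d
            R[:, j] = Rp @ _rot_batch(axis, Q[:, j - 1])
            w[:, j] = w[:, parent] + s * qdj
            al[:, j] = al[:, parent] + s * qddj + np.cross(w[:, parent], s * qdj)
            a[:, j] = (
                a[:, parent]
                + np.cross(al[:, parent], d)
                + np.cross(w[:, parent], np.cross(w[:, parent], d))
            )
    f = np.zeros((nt, n + 1, 3))
    nm = np.zeros((nt, n + 1, 3))
    for i, (jb, offset, _ax) in enumerate(struct.bodies):
        m = model.link_masses[i]
        r = R[:, jb] @ offset
        a_c = a[:, jb] + np.cross(al[:, jb], r) + np.cross(w[:, jb], np.cross(w[:, jb], r))
        Iw = R[:, jb] @ struct.inertias[i] @ np.swapaxes(R[:, jb], 1, 2)
        F = m * (a_c - gvec)
        Nm = (Iw @ al[:, jb][..., None])[..., 0] + np.cross(
            w[:, jb], (Iw @ w[:, jb][..., None])[..., 0]
        )
        f[:, jb] += F
        nm[:, jb] += Nm + np.cross(r, F)
    tau = np.zeros((nt, n))
    for j in range(n, 0, -1):
        parent, kind, _axis, _trans = joints[j]
        vec = f[:, j] if kind == "p" else nm[:, j]
        tau[:, j - 1] = np.einsum("ti,ti->t", s_ax[:, j], vec)
        if parent > 0:
            f[:, parent] += f[:, j]
            nm[:, parent] += nm[:, j] + np.cross(o[:, j] - o[:, parent], f[:, j])
    return tau


def batch_mass_matrix(model, Q, fk=None):
    """Mass matrices (nt, 33, 33) from batched link Jacobians."""
    Q = np.asarray(Q, float)
    nt = Q.shape[0]
    if fk is None:
        fk = batch_fk(model, Q)
    origins, rotations, axes = fk
    struct = model.structure()
    A = np.zeros((nt, N_COORDS, N_COORDS))
    for i, (jb, offset, _ax) in enumerate(struct.bodies):
        c = origins[:, jb] + rotations[:, jb] @ offset
        Jv = np.zeros((nt, 3, N_COORDS))
        Jw = np.zeros((nt, 3, N_COORDS))
        for j in struct.ancestors[jb]:
            kind = struct.joints[j][1]
            s = axes[:, j]
            if kind == "p":
                Jv[:, :, j - 1] = s
            else:
                Jv[:, :, j - 1] = np.cross(s, c - origins[:, j])
                Jw[:, :, j - 1] = s
        m = model.link_masses[i]
        Iw = rotations[:, jb] @ struct.inertias[i] @ np.swapaxes(rotations[:, jb], 1, 2)
        A += m * np.swapaxes(Jv, 1, 2) @ Jv + np.swapaxes(Jw, 1, 2) @ Iw @ Jw
    return A


def batch_contact_jacobian(model, Q, side, fk=None):
    """Tiptoe point Jacobians (nt, 3, 33) for one foot along a trace."""
    Q = np.asarray(Q, float)
    nt = Q.shape[0]
    if fk is None:
        fk = batch_fk(model, Q)
    origins, rotations, axes = fk
    struct = model.structure()
    foot_joint = 26 if side == "left" else 33
    lf = model.link_lengths[11 if side == "left" else 14]
    tip = origins[:, foot_joint] + rotations[:, foot_joint] @ np.array([lf, 0.0, 0.0])
    J = np.zeros((nt, 3, N_COORDS))
    for j in struct.ancestors[foot_joint]:
        kind = struct.joints[j][1]
        s = axes[:, j]
        if kind == "p":
            J[:, :, j - 1] = s
        else:
            J[:, :, j - 1] = np.cross(s, tip - origins[:, j])
    return J, tip
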