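"""Joint-space and contact dynamics of the 33-coordinate biomechanical model.

Provides the equation-of-motion terms ``A(q) q̈ + b(q, q̇) + g(q) = Γ``, the
contact Jacobian of the stance tiptoe, the operational-space contact
quantities (task inertia Λ_c, bias μ_c, gravity p_c, dynamically consistent
transpose J̄_cᵀ), contact-force recovery for a foot fixed on the ground, and
inverse dynamics with or without contact.

The mass matrix is assembled from per-link geometric Jacobians
(``A = Σ m J_vᵀ J_v + J_ωᵀ I_w J_ω``); the bias and gravity vectors come
from a recursive Newton-Euler pass.  With contact, the torque equation is
implicit and its system matrix ``I − J_cᵀ J̄_cᵀ`` is a singular projector
(contact makes the actuation redundant); the minimum-norm solution is
returned.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .biomech import N_COORDS, BiomechModel, forward_kinematics, rot

__all__ = [
    "GRAVITY",
    "DynamicsTerms",
    "ContactOperationalSpace",
    "rnea",
    "dynamics_terms",
    "body_jacobians",
    "contact_jacobian",
    "contact_jacobian_dot",
    "operational_space",
    "contact_force",
    "inverse_dynamics",
    "kinetic_energy",
]

GRAVITY = 9.81

_UNIT = {"x": np.array([1.0, 0, 0]), "y": np.array([0, 1.0, 0]), "z": np.array([0, 0, 1.0])}


def _gravity_vec(gravity):
    if gravity is None:
        return np.zeros(3)
    if np.isscalar(gravity):
        return np.array([0.0, 0.0, -float(gravity)])
    return np.asarray(gravity, float)


def rnea(
    model: BiomechModel,
    q: np.ndarray,
    qdot: np.ndarray,
    qddot: np.ndarray,
    gravity=GRAVITY,
) -> np.ndarray:
    """Recursive Newton-Euler inverse dynamics: Γ = A q̈ + b + g (no contact)."""
    q = np.asarray(q, float)
    qdot = np.asarray(qdot, float)
    qddot = np.asarray(qddot, float)
    gvec = _gravity_vec(gravity)
    struct = model.structure()
    joints = struct.joints
    n = N_COORDS
    # forward pass
    R = np.zeros((n + 1, 3, 3))
    o = np.zeros((n + 1, 3))
    w = np.zeros((n + 1, 3))
    al = np.zeros((n + 1, 3))
    v = np.zeros((n + 1, 3))
    a = np.zeros((n + 1, 3))
    s_axis = np.zeros((n + 1, 3))
    R[0] = np.eye(3)
    for j in range(1, n + 1):
        parent, kind, axis, trans = joints[j]
        Rp = R[parent]
        s = Rp @ _UNIT[axis]
        s_axis[j] = s
        if kind == "p":
            d = Rp @ trans + s * q[j - 1]
            o[j] = o[parent] + d
            R[j] = Rp
            w[j] = w[parent]
            al[j] = al[parent]
            v[j] = v[parent] + np.cross(w[parent], d) + s * qdot[j - 1]
            a[j] = (
                a[parent]
                + np.cross(al[parent], d)
                + np.cross(w[parent], np.cross(w[parent], d))
                + 2.0 * np.cross(w[parent], s * qdot[j - 1])
                + s * qddot[j - 1]
            )
        else:
            d = Rp @ trans
            o[j] = o[parent] + d
            R[j] = Rp @ rot(axis, q[j - 1])
            w[j] = w[parent] + s * qdot[j - 1]
            al[j] = al[parent] + s * qddot[j - 1] + np.cross(w[parent], s * qdot[j - 1])
            v[j] = v[parent] + np.cross(w[parent], d)
            a[j] = (
                a[parent]
                + np.cross(al[parent], d)
                + np.cross(w[parent], np.cross(w[parent], d))
            )
    # body wrenches accumulated at the supporting joint origins
    f = np.zeros((n + 1, 3))
    nmom = np.zeros((n + 1, 3))
    for i, (jb, offset, _ax) in enumerate(struct.bodies):
        m = model.link_masses[i]
        r = R[jb] @ offset
        a_c = a[jb] + np.cross(al[jb], r) + np.cross(w[jb], np.cross(w[jb], r))
        Iw = R[jb] @ struct.inertias[i] @ R[jb].T
        F = m * (a_c - gvec)
        N = Iw @ al[jb] + np.cross(w[jb], Iw @ w[jb])
        f[jb] += F
        nmom[jb] += N + np.cross(r, F)
    # backward pass
    tau = np.zeros(n)
    for j in range(n, 0, -1):
        parent, kind, _axis, _trans = joints[j]
        tau[j - 1] = s_axis[j] @ (f[j] if kind == "p" else nmom[j])
        if parent > 0:
            f[parent] += f[j]
            nmom[parent] += nmom[j] + np.cross(o[j] - o[parent], f[j])
    return tau


def _ancestors(model: BiomechModel):
    return model.structure().ancestors


def body_jacobians(model: BiomechModel, q: np.ndarray):
    """Linear and angular geometric Jacobians (3x33 each) of every link COM."""
    fk = forward_kinematics(model, q)
    struct = model.structure()
    joints = struct.joints
    anc = struct.ancestors
    Jv = np.zeros((15, 3, N_COORDS))
    Jw = np.zeros((15, 3, N_COORDS))
    for i, (jb, offset, _ax) in enumerate(struct.bodies):
        c = fk.origins[jb] + fk.rotations[jb] @ offset
        for j in anc[jb]:
            kind = joints[j][1]
            s = fk.axes[j]
            if kind == "p":
                Jv[i][:, j - 1] = s
            else:
                Jv[i][:, j - 1] = np.cross(s, c - fk.origins[j])
                Jw[i][:, j - 1] = s
    return fk, Jv, Jw


@dataclass
class DynamicsTerms:
    """Joint-space inertia matrix, bias vector and gravity vector."""

    inertia: np.ndarray  # (33, 33), symmetric positive definite
    bias: np.ndarray  # (33,) Coriolis/centrifugal, zero at rest
    gravity: np.ndarray  # (33,)


def dynamics_terms(
    model: BiomechModel, q: np.ndarray, qdot: np.ndarray, gravity=GRAVITY
) -> DynamicsTerms:
    """A(q), b(q, q̇) and g(q) of the 33-coordinate equation of motion."""
    _fk, Jv, Jw = body_jacobians(model, q)
    A = np.zeros((N_COORDS, N_COORDS))
    fkR = _fk.rotations
    struct = model.structure()
    for i, (jb, _off, _ax) in enumerate(struct.bodies):
        m = model.link_masses[i]
        Iw = fkR[jb] @ struct.inertias[i] @ fkR[jb].T
        A += m * Jv[i].T @ Jv[i] + Jw[i].T @ Iw @ Jw[i]
    bias_plus_g = rnea(model, q, qdot, np.zeros(N_COORDS), gravity)
    gvec = rnea(model, q, np.zeros(N_COORDS), np.zeros(N_COORDS), gravity)
    return DynamicsTerms(inertia=A, bias=bias_plus_g - gvec, gravity=gvec)


def kinetic_energy(model: BiomechModel, q: np.ndarray, qdot: np.ndarray) -> float:
    """½ q̇ᵀ A(q) q̇ via the assembled mass matrix."""
    A = dynamics_terms(model, q, np.zeros(N_COORDS), gravity=None).inertia
    return 0.5 * float(qdot @ A @ qdot)


# --------------------------------------------------------------------------
# contact


def contact_jacobian(
    model: BiomechModel, q: np.ndarray, side: str, rows: str = "point"
) -> np.ndarray:
    """Jacobian of the stance tiptoe: ẋ_c = J_c q̇.

    ``rows='point'`` gives the 3 linear rows of the tiptoe point (a point
    foot cannot transmit moments); ``rows='wrench'`` appends the 3 angular
    rows of the foot segment.
    """
    if side not in ("left", "right"):
        raise ValueError("no active contact side")
    fk = forward_kinematics(model, q)
    struct = model.structure()
    joints = struct.joints
    anc = struct.ancestors
    tip = fk.landmarks[f"tiptoe_{side}"]
    foot_joint = 26 if side == "left" else 33
    Jlin = np.zeros((3, N_COORDS))
    Jang = np.zeros((3, N_COORDS))
    for j in anc[foot_joint]:
        kind = joints[j][1]
        s = fk.axes[j]
        if kind == "p":
            Jlin[:, j - 1] = s
        else:
            Jlin[:, j - 1] = np.cross(s, tip - fk.origins[j])
            Jang[:, j - 1] = s
    if rows == "point":
        return Jlin
    if rows == "wrench":
        return np.vstack([Jlin, Jang])
    raise ValueError("rows must be 'point' or 'wrench'")


def contact_jacobian_dot(
    model: BiomechModel,
    q: np.ndarray,
    qdot: np.ndarray,
    side: str,
    rows: str = "point",
    eps: float = 1e-6,
) -> np.ndarray:
    """J̇_c by central finite differences of J_c along the trajectory."""
    qdot = np.asarray(qdot, float)
    Jp = contact_jacobian(model, q + eps * qdot, side, rows)
    Jm = contact_jacobian(model, q - eps * qdot, side, rows)
    return (Jp - Jm) / (2.0 * eps)


@dataclass
class ContactOperationalSpace:
    """Operational-space contact quantities at the stance foot."""

    jacobian: np.ndarray  # J_c
    jacobian_dot: np.ndarray
    task_inertia: np.ndarray  # Λ_c = (J_c A⁻¹ J_cᵀ)⁻¹
    task_bias: np.ndarray  # μ_c
    task_gravity: np.ndarray  # p_c
    dyn_consistent_transpose: np.ndarray  # J̄_cᵀ = Λ_c J_c A⁻¹


def operational_space(
    model: BiomechModel,
    q: np.ndarray,
    qdot: np.ndarray,
    J_c: np.ndarray,
    J_c_dot: np.ndarray,
    terms: DynamicsTerms | None = None,
    gravity=GRAVITY,
    cond_limit: float = 1e12,
) -> ContactOperationalSpace:
    """Λ_c, μ_c, p_c and J̄_cᵀ per the operational-space formulation."""
    if terms is None:
        terms = dynamics_terms(model, q, qdot, gravity)
    Ainv_JT = np.linalg.solve(terms.inertia, J_c.T)
    JAinvJT = J_c @ Ainv_JT
    if np.linalg.cond(JAinvJT) > cond_limit:
        raise np.linalg.LinAlgError(
            "contact Jacobian is rank deficient at this pose (kinematic singularity)"
        )
    Lam = np.linalg.inv(JAinvJT)
    mu = Lam @ (Ainv_JT.T @ terms.bias - J_c_dot @ qdot)
    p = Lam @ (Ainv_JT.T @ terms.gravity)
    JbarT = Lam @ Ainv_JT.T
    return ContactOperationalSpace(
        jacobian=J_c,
        jacobian_dot=J_c_dot,
        task_inertia=Lam,
        task_bias=mu,
        task_gravity=p,
        dyn_consistent_transpose=JbarT,
    )


def contact_force(Gamma: np.ndarray, ops: ContactOperationalSpace) -> np.ndarray:
    """Reaction at the fixed foot: f_c = J̄_cᵀ Γ − μ_c − p_c."""
    return ops.dyn_consistent_transpose @ Gamma - ops.task_bias - ops.task_gravity


def inverse_dynamics(
    model: BiomechModel,
    q: np.ndarray,
    qdot: np.ndarray,
    qddot: np.ndarray,
    contact: str | None = None,
    rows: str = "point",
    gravity=GRAVITY,
    terms: DynamicsTerms | None = None,
    consistency_tol: float | None = None,
    resolution: str = "no_base_force",
):
    """Joint torques Γ for the prescribed motion, with or without contact.

    Without contact ``Γ = A q̈ + b + g``.  With a foot fixed on the ground
    the torque equation ``(I − J_cᵀ J̄_cᵀ) Γ = A q̈ + b + g − J_cᵀ (μ_c + p_c)``
    has a singular projector as system matrix (contact makes actuation
    redundant); the solution family is a minimum-norm member plus
    ``J_cᵀ λ``.  ``resolution='no_base_force'`` (default) spends the
    freedom so the unactuated virtual translations carry no torque (the
    base cannot push the animal), minimum-norm over the remainder;
    ``resolution='min_norm'`` returns the plain minimum-norm member.  If
    ``consistency_tol`` is set, a contact acceleration
    ``J_c q̈ + J̇_c q̇`` exceeding it raises.
    """
    q = np.asarray(q, float)
    qdot = np.asarray(qdot, float)
    qddot = np.asarray(qddot, float)
    if terms is None:
        terms = dynamics_terms(model, q, qdot, gravity)
    tau_free = terms.inertia @ qddot + terms.bias + terms.gravity
    if contact is None:
        return tau_free, None
    J = contact_jacobian(model, q, contact, rows)
    Jdot = contact_jacobian_dot(model, q, qdot, contact, rows)
    if consistency_tol is not None:
        resid = np.linalg.norm(J @ qddot + Jdot @ qdot)
        if resid > consistency_tol:
            raise ValueError(
                f"contact acceleration residual {resid:.3e} exceeds tolerance"
            )
    ops = operational_space(model, q, qdot, J, Jdot, terms=terms, gravity=gravity)
    P = np.eye(N_COORDS) - J.T @ ops.dyn_consistent_transpose
    rhs = tau_free - J.T @ (ops.task_bias + ops.task_gravity)
    Gamma, *_ = np.linalg.lstsq(P, rhs, rcond=None)
    if resolution == "no_base_force":
        Gamma = Gamma + J[:2].T @ (-Gamma[:2])
        Jz = J[2]
        Gamma = Gamma - (Gamma @ Jz) / (Jz @ Jz) * Jz
    elif resolution != "min_norm":
        raise ValueError("resolution must be 'no_base_force' or 'min_norm'")
    return Gamma, contact_force(Gamma, ops)
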