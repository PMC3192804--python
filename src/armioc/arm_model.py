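"""Planar two-link arm moving in the vertical (para-sagittal) plane.

The arm is a shoulder-elbow linkage with the shoulder at the origin of an
(x, z) frame: x antero-posterior (forward positive), z vertical (up
positive).  Joint angle ``q1`` is measured counterclockwise from the +x
axis to the upper arm, ``q2`` counterclockwise from the upper-arm
extension to the forearm (elbow flexion positive).

Rigid-body dynamics take the standard manipulator form

    M(q) q̈ + C(q, q̇) q̇ + G(q) + B q̇ = τ,

with inertia matrix M, Coriolis/centripetal matrix C, gravity vector G and
a constant joint-viscosity matrix B.  Torques are not controlled directly:
the neural command is the torque acceleration, u = τ̈, so the full state is
(q, q̇, τ, τ̇) and the arm is differentially flat in q(t) — every state and
the control follow from q and its time derivatives up to fourth order.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "ArmParams",
    "ArmState",
    "forward_kinematics",
    "fingertip_chain",
    "inverse_kinematics",
    "mass_matrix",
    "coriolis_matrix",
    "coriolis_vector",
    "gravity_vector",
    "potential_energy",
    "kinetic_energy",
    "inverse_dynamics",
    "torque_rate",
    "torque_accel",
    "dynamics_rhs",
]

# Winter-style anthropometric regressions: segment mass as a fraction of
# body mass, segment length as a fraction of stature, COM and gyration
# radius as fractions of segment length (forearm segment includes hand).
_SEG = {
    "upper_arm": dict(mass=0.028, length=0.186, com=0.436, gyr=0.322),
    "forearm_hand": dict(mass=0.022, length=0.254, com=0.682, gyr=0.468),
}


@dataclass(frozen=True)
class ArmParams:
    """Inertial and geometric parameters of the two-link arm (SI units)."""

    l1: float = 0.3255  # upper-arm length (m)
    l2: float = 0.4445  # forearm+hand length (m)
    m1: float = 1.96  # upper-arm mass (kg)
    m2: float = 1.54  # forearm+hand mass (kg)
    lc1: float = 0.141918  # shoulder -> upper-arm COM (m)
    lc2: float = 0.303149  # elbow -> forearm COM (m)
    I1: float = 0.0215313  # upper-arm inertia about its COM (kg m^2)
    I2: float = 0.0666432  # forearm inertia about its COM (kg m^2)
    B: np.ndarray = field(
        default_factory=lambda: np.array([[0.05, 0.025], [0.025, 0.05]])
    )  # joint viscosity (N m s / rad)
    g: float = 9.81  # gravitational acceleration (m/s^2)
    q_min: tuple = (-np.pi / 2, 0.0)  # joint limits (rad)
    q_max: tuple = (np.pi, 2.8)
    u_max: float = 10000.0  # |τ̈| bound (N m / s^2)

    def __post_init__(self):
        B = np.asarray(self.B, dtype=float)
        object.__setattr__(self, "B", B)
        for name in ("l1", "l2", "m1", "m2", "lc1", "lc2", "I1", "I2"):
            if getattr(self, name) <= 0:
                raise ValueError(f"ArmParams.{name} must be > 0")
        if self.lc1 > self.l1 or self.lc2 > self.l2:
            raise ValueError("COM offsets must not exceed segment lengths")
        if B.shape != (2, 2) or not np.allclose(B, B.T):
            raise ValueError("viscosity matrix B must be symmetric 2x2")
        if np.any(np.linalg.eigvalsh(B) < -1e-12):
            raise ValueError("viscosity matrix B must be positive semi-definite")
        if self.g < 0:
            raise ValueError("g must be >= 0 (magnitude of gravity)")

    @property
    def L(self) -> float:
        """Total arm length l1 + l2 (m)."""
        return self.l1 + self.l2

    # inertia shorthand: M11 = a + 2 b cos q2, M12 = M22 + b cos q2, M22 = d
    @property
    def _a(self) -> float:
        return self.I1 + self.I2 + self.m1 * self.lc1**2 + self.m2 * (
            self.l1**2 + self.lc2**2
        )

    @property
    def _b(self) -> float:
        return self.m2 * self.l1 * self.lc2

    @property
    def _d(self) -> float:
        return self.I2 + self.m2 * self.lc2**2

    @classmethod
    def from_anthropometry(cls, body_mass: float = 70.0, height: float = 1.75, **kw):
        """Scale segment parameters from body mass (kg) and stature (m)."""
        ua, fa = _SEG["upper_arm"], _SEG["forearm_hand"]
        l1 = ua["length"] * height
        l2 = fa["length"] * height
        m1 = ua["mass"] * body_mass
        m2 = fa["mass"] * body_mass
        out = cls(
            l1=l1, l2=l2, m1=m1, m2=m2,
            lc1=ua["com"] * l1, lc2=fa["com"] * l2,
            I1=m1 * (ua["gyr"] * l1) ** 2, I2=m2 * (fa["gyr"] * l2) ** 2,
            **kw,
        )
        return out

    def replace(self, **kw) -> "ArmParams":
        return replace(self, **kw)

    def to_dict(self) -> dict:
        return {
            "l1": self.l1, "l2": self.l2, "m1": self.m1, "m2": self.m2,
            "lc1": self.lc1, "lc2": self.lc2, "I1": self.I1, "I2": self.I2,
            "B": np.asarray(self.B).tolist(), "g": self.g,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ArmParams":
        d = dict(d)
        if "B" in d:
            d["B"] = np.asarray(d["B"], dtype=float)
        return cls(**d)


@dataclass
class ArmState:
    """Full state of the torque-actuated arm: (q, q̇, τ, τ̇)."""

    q: np.ndarray
    qdot: np.ndarray
    tau: np.ndarray
    taudot: np.ndarray

    def as_vector(self) -> np.ndarray:
        return np.concatenate([self.q, self.qdot, self.tau, self.taudot])

    @classmethod
    def from_vector(cls, x: np.ndarray) -> "ArmState":
        x = np.asarray(x, dtype=float)
        return cls(q=x[0:2], qdot=x[2:4], tau=x[4:6], taudot=x[6:8])

    @classmethod
    def rest(cls, q: np.ndarray, params: ArmParams) -> "ArmState":
        """Static equilibrium at posture q: zero velocity, gravity-balancing torque."""
        q = np.asarray(q, dtype=float)
        return cls(q=q, qdot=np.zeros(2), tau=gravity_vector(q, params),
                   taudot=np.zeros(2))


# ---------------------------------------------------------------------------
# kinematics


def forward_kinematics(q, params: ArmParams):
    """Fingertip position (x, z) for joint angles q = (q1, q2).

    Accepts a trailing-axis-2 array of angles; returns matching-shape
    positions.  x = l1 cos q1 + l2 cos(q1+q2), z = l1 sin q1 + l2 sin(q1+q2).
    """
    q = np.asarray(q, dtype=float)
    q1 = q[..., 0]
    q12 = q1 + q[..., 1]
    x = params.l1 * np.cos(q1) + params.l2 * np.cos(q12)
    z = params.l1 * np.sin(q1) + params.l2 * np.sin(q12)
    return np.stack([x, z], axis=-1)


def fingertip_chain(q, qdot=None, qddot=None, qdddot=None, *, params: ArmParams):
    """Fingertip position and time derivatives up to jerk by the chain rule.

    Uses the complex representation p = l1 e^{i q1} + l2 e^{i(q1+q2)}; each
    rotating unit vector e^{iθ(t)} differentiates to
    (iθ̇)e^{iθ}, (iθ̈ − θ̇²)e^{iθ}, (iθ⃛ − 3θ̇θ̈ − iθ̇³)e^{iθ}.
    Returns the tuple (pos, vel, acc, jerk) truncated to the derivatives
    supplied, each an (..., 2) array of (x, z) components.
    """
    q = np.asarray(q, dtype=float)
    th1 = q[..., 0]
    th2 = q[..., 0] + q[..., 1]
    e1 = params.l1 * np.exp(1j * th1)
    e2 = params.l2 * np.exp(1j * th2)

    def _split(c):
        return np.stack([c.real, c.imag], axis=-1)

    out = [_split(e1 + e2)]
    if qdot is None:
        return tuple(out)
    qdot = np.asarray(qdot, dtype=float)
    w1 = qdot[..., 0]
    w2 = qdot[..., 0] + qdot[..., 1]
    out.append(_split(1j * w1 * e1 + 1j * w2 * e2))
    if qddot is None:
        return tuple(out)
    qddot = np.asarray(qddot, dtype=float)
    a1 = qddot[..., 0]
    a2 = qddot[..., 0] + qddot[..., 1]
    out.append(_split((1j * a1 - w1**2) * e1 + (1j * a2 - w2**2) * e2))
    if qdddot is None:
        return tuple(out)
    qdddot = np.asarray(qdddot, dtype=float)
    j1 = qdddot[..., 0]
    j2 = qdddot[..., 0] + qdddot[..., 1]
    out.append(_split((1j * j1 - 3 * w1 * a1 - 1j * w1**3) * e1
                      + (1j * j2 - 3 * w2 * a2 - 1j * w2**3) * e2))
    return tuple(out)


def inverse_kinematics(p, params: ArmParams, branch: str = "positive"):
    """Joint angles reaching fingertip position p = (x, z).

    ``branch="positive"`` selects the elbow configuration with q2 in [0, π]
    (flexed elbow, the physiological branch); ``"negative"`` mirrors it.

    Raises ValueError when p lies outside the reachable annulus
    |l1 − l2| ≤ |p| ≤ l1 + l2.
    """
    p = np.asarray(p, dtype=float)
    x, z = p[..., 0], p[..., 1]
    r2 = x**2 + z**2
    r = np.sqrt(r2)
    lo, hi = abs(params.l1 - params.l2), params.l1 + params.l2
    tol = 1e-9
    if np.any(r > hi + tol):
        raise ValueError(
            f"point at distance {float(np.max(r)):.4f} m exceeds arm length {hi:.4f} m"
        )
    if np.any(r < lo - tol):
        raise ValueError(
            f"point at distance {float(np.min(r)):.4f} m is inside the inner "
            f"workspace boundary |l1-l2| = {lo:.4f} m"
        )
    c2 = (r2 - params.l1**2 - params.l2**2) / (2 * params.l1 * params.l2)
    c2 = np.clip(c2, -1.0, 1.0)
    q2 = np.arccos(c2)
    if branch == "negative":
        q2 = -q2
    elif branch != "positive":
        raise ValueError(f"unknown branch {branch!r}")
    q1 = np.arctan2(z, x) - np.arctan2(
        params.l2 * np.sin(q2), params.l1 + params.l2 * np.cos(q2)
    )
    return np.stack([np.asarray(q1), np.asarray(q2)], axis=-1)


# ---------------------------------------------------------------------------
# dynamics


def mass_matrix(q, params: ArmParams):
    """Inertia matrix M(q), shape (..., 2, 2); symmetric positive definite."""
    q = np.asarray(q, dtype=float)
    c2 = np.cos(q[..., 1])
    a, b, d = params._a, params._b, params._d
    M = np.empty(q.shape[:-1] + (2, 2))
    M[..., 0, 0] = a + 2 * b * c2
    M[..., 0, 1] = d + b * c2
    M[..., 1, 0] = d + b * c2
    M[..., 1, 1] = d
    return M


def coriolis_matrix(q, qdot, params: ArmParams):
    """Coriolis matrix C(q, q̇) in the convention making Ṁ − 2C skew-symmetric."""
    q = np.asarray(q, dtype=float)
    qdot = np.asarray(qdot, dtype=float)
    bs2 = params._b * np.sin(q[..., 1])
    w1, w2 = qdot[..., 0], qdot[..., 1]
    C = np.empty(q.shape[:-1] + (2, 2))
    C[..., 0, 0] = -bs2 * w2
    C[..., 0, 1] = -bs2 * (w1 + w2)
    C[..., 1, 0] = bs2 * w1
    C[..., 1, 1] = 0.0
    return C


def coriolis_vector(q, qdot, params: ArmParams):
    """The vector h(q, q̇) = C(q, q̇) q̇."""
    q = np.asarray(q, dtype=float)
    qdot = np.asarray(qdot, dtype=float)
    bs2 = params._b * np.sin(q[..., 1])
    w1, w2 = qdot[..., 0], qdot[..., 1]
    return np.stack([-bs2 * (2 * w1 * w2 + w2**2), bs2 * w1**2], axis=-1)


def gravity_vector(q, params: ArmParams):
    """Gravity torque vector G(q) = ∂V/∂q."""
    q = np.asarray(q, dtype=float)
    q1 = q[..., 0]
    q12 = q1 + q[..., 1]
    g1 = (params.m1 * params.lc1 + params.m2 * params.l1) * params.g
    g2 = params.m2 * params.lc2 * params.g
    return np.stack([g1 * np.cos(q1) + g2 * np.cos(q12), g2 * np.cos(q12)], axis=-1)


def potential_energy(q, params: ArmParams):
    """Gravitational potential energy (J), zero level at the shoulder height."""
    q = np.asarray(q, dtype=float)
    q1 = q[..., 0]
    q12 = q1 + q[..., 1]
    return (
        params.m1 * params.g * params.lc1 * np.sin(q1)
        + params.m2 * params.g * (params.l1 * np.sin(q1) + params.lc2 * np.sin(q12))
    )


def kinetic_energy(q, qdot, params: ArmParams):
    """Kinetic energy ½ q̇ᵀ M(q) q̇ (J)."""
    M = mass_matrix(q, params)
    qdot = np.asarray(qdot, dtype=float)
    return 0.5 * np.einsum("...i,...ij,...j->...", qdot, M, qdot)


def inverse_dynamics(q, qdot, qddot, params: ArmParams):
    """Torque realizing the joint acceleration: τ = M q̈ + h + G + B q̇."""
    qdot = np.asarray(qdot, dtype=float)
    qddot = np.asarray(qddot, dtype=float)
    M = mass_matrix(q, params)
    return (
        np.einsum("...ij,...j->...i", M, qddot)
        + coriolis_vector(q, qdot, params)
        + gravity_vector(q, params)
        + qdot @ params.B.T
    )


def _mass_matrix_dot(q, qdot, params: ArmParams):
    q = np.asarray(q, dtype=float)
    s2 = np.sin(q[..., 1])
    w2 = np.asarray(qdot, dtype=float)[..., 1]
    k = -params._b * s2 * w2
    Md = np.empty(q.shape[:-1] + (2, 2))
    Md[..., 0, 0] = 2 * k
    Md[..., 0, 1] = k
    Md[..., 1, 0] = k
    Md[..., 1, 1] = 0.0
    return Md


def torque_rate(q, qdot, qddot, qdddot, params: ArmParams):
    """Time derivative of the inverse-dynamics torque, τ̇, along a motion.

    τ̇ = Ṁ q̈ + M q⃛ + ḣ + Ġ + B q̈, all terms expanded in closed form.
    """
    q, qdot, qddot, qdddot = (np.asarray(v, dtype=float) for v in
                              (q, qdot, qddot, qdddot))
    b = params._b
    s2, c2 = np.sin(q[..., 1]), np.cos(q[..., 1])
    w1, w2 = qdot[..., 0], qdot[..., 1]
    a1, a2 = qddot[..., 0], qddot[..., 1]
    M = mass_matrix(q, params)
    Md = _mass_matrix_dot(q, qdot, params)
    # ḣ where h = b s2 * v, v = (-(2 w1 w2 + w2²), w1²)
    v = np.stack([-(2 * w1 * w2 + w2**2), w1**2], axis=-1)
    vd = np.stack([-(2 * a1 * w2 + 2 * w1 * a2 + 2 * w2 * a2), 2 * w1 * a1], axis=-1)
    hd = b * (c2 * w2)[..., None] * v + b * s2[..., None] * vd
    # Ġ
    q1 = q[..., 0]
    q12 = q1 + q[..., 1]
    g1 = (params.m1 * params.lc1 + params.m2 * params.l1) * params.g
    g2 = params.m2 * params.lc2 * params.g
    w12 = w1 + w2
    Gd = np.stack(
        [-g1 * np.sin(q1) * w1 - g2 * np.sin(q12) * w12, -g2 * np.sin(q12) * w12],
        axis=-1,
    )
    return (
        np.einsum("...ij,...j->...i", Md, qddot)
        + np.einsum("...ij,...j->...i", M, qdddot)
        + hd + Gd + qddot @ params.B.T
    )


def torque_accel(q, qdot, qddot, qdddot, qddddot, params: ArmParams):
    """Second time derivative of the torque, τ̈ = u (the neural command)."""
    q, qdot, qddot, qdddot, qddddot = (np.asarray(v, dtype=float) for v in
                                       (q, qdot, qddot, qdddot, qddddot))
    b = params._b
    s2, c2 = np.sin(q[..., 1]), np.cos(q[..., 1])
    w1, w2 = qdot[..., 0], qdot[..., 1]
    a1, a2 = qddot[..., 0], qddot[..., 1]
    j1, j2 = qdddot[..., 0], qdddot[..., 1]
    M = mass_matrix(q, params)
    Md = _mass_matrix_dot(q, qdot, params)
    # M̈ entries: d/dt(-b s2 w2) = -b (c2 w2² + s2 a2)
    k2 = -b * (c2 * w2**2 + s2 * a2)
    Mdd = np.empty(M.shape)
    Mdd[..., 0, 0] = 2 * k2
    Mdd[..., 0, 1] = k2
    Mdd[..., 1, 0] = k2
    Mdd[..., 1, 1] = 0.0
    # ḧ: h = b s2 v; ḧ = b[(−s2 w2² + c2 a2) v + 2 c2 w2 v̇ + s2 v̈]
    v = np.stack([-(2 * w1 * w2 + w2**2), w1**2], axis=-1)
    vd = np.stack([-(2 * a1 * w2 + 2 * w1 * a2 + 2 * w2 * a2), 2 * w1 * a1], axis=-1)
    vdd = np.stack(
        [-(2 * j1 * w2 + 4 * a1 * a2 + 2 * w1 * j2 + 2 * a2**2 + 2 * w2 * j2),
         2 * (a1**2 + w1 * j1)],
        axis=-1,
    )
    hdd = (
        b * (-s2 * w2**2 + c2 * a2)[..., None] * v
        + 2 * b * (c2 * w2)[..., None] * vd
        + b * s2[..., None] * vdd
    )
    # G̈
    q1 = q[..., 0]
    q12 = q1 + q[..., 1]
    g1 = (params.m1 * params.lc1 + params.m2 * params.l1) * params.g
    g2 = params.m2 * params.lc2 * params.g
    w12, a12 = w1 + w2, a1 + a2
    t1 = np.cos(q1) * w1**2 + np.sin(q1) * a1
    t12 = np.cos(q12) * w12**2 + np.sin(q12) * a12
    Gdd = np.stack([-g1 * t1 - g2 * t12, -g2 * t12], axis=-1)
    return (
        np.einsum("...ij,...j->...i", Mdd, qddot)
        + 2 * np.einsum("...ij,...j->...i", Md, qdddot)
        + np.einsum("...ij,...j->...i", M, qddddot)
        + hdd + Gdd + qdddot @ params.B.T
    )


def dynamics_rhs(state, u, params: ArmParams):
    """State derivative of the torque-actuated arm: ẋ = f(x, u).

    state is an ArmState or flat 8-vector (q, q̇, τ, τ̇); u = τ̈ (2-vector).
    Returns the flat 8-vector (q̇, q̈, τ̇, τ̈) with
    q̈ = M(q)⁻¹ (τ − h(q, q̇) − G(q) − B q̇).
    """
    if isinstance(state, ArmState):
        state = state.as_vector()
    x = np.asarray(state, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite state passed to dynamics_rhs")
    q, qdot, tau, taudot = x[0:2], x[2:4], x[4:6], x[6:8]
    M = mass_matrix(q, params)
    rhs = tau - coriolis_vector(q, qdot, params) - gravity_vector(q, params) \
        - params.B @ qdot
    qddot = np.linalg.solve(M, rhs)
    return np.concatenate([qdot, qddot, taudot, np.asarray(u, dtype=float)])
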