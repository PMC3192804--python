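"""Movement cost functionals for planar reaching.

Eight classical candidate costs from the motor-control literature are
evaluated on a common trajectory representation and combined linearly into
composite (hybrid) costs:

====  =============  =====================================================
 id    name           integrand over the movement [0, T]
====  =============  =====================================================
 C1    hand_jerk      ‖fingertip jerk‖²          (Cartesian smoothness)
 C2    angle_jerk     ‖q⃛‖²                       (joint smoothness)
 C3    angle_accel    ‖q̈‖²                       (joint smoothness)
 C4    torque_change  ‖τ̇‖²
 C5    torque         ‖τ‖²
 C6    geodesic       √(q̇ᵀM(q)q̇)                (kinetic-energy path length)
 C7    energy         Σᵢ |τᵢ q̇ᵢ|                 (total absolute work)
 C8    effort         ‖u‖² with u = τ̈            (neural command)
====  =============  =====================================================

The two nonsmooth integrands (geodesic, energy) are regularized with a
smoothing parameter ``eps``: √(·+eps) and √((·)²+eps²) respectively, which
converge to the exact values from above as eps → 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.interpolate import CubicSpline

from .arm_model import (
    ArmParams,
    fingertip_chain,
    inverse_dynamics,
    mass_matrix,
    torque_accel,
    torque_rate,
)

__all__ = ["BASIS_COSTS", "CostWeights", "Trajectory", "basis_cost",
           "all_basis_costs", "composite_cost", "cost_contributions"]

BASIS_COSTS = (
    "hand_jerk",
    "angle_jerk",
    "angle_accel",
    "torque_change",
    "torque",
    "geodesic",
    "energy",
    "effort",
)
_INDEX = {name: i for i, name in enumerate(BASIS_COSTS)}


@dataclass
class CostWeights:
    """Non-negative weights over the eight basis costs.

    ``alpha`` are the raw weights; ``s`` is a positive re-scaling vector
    bringing the differently-dimensioned basis costs to comparable
    magnitude, so the composite is Σᵢ αᵢ sᵢ Cᵢ.  ``anchor`` marks the
    component conventionally fixed to 1 during inverse optimization
    (default: angle_accel).
    """

    alpha: np.ndarray
    s: np.ndarray = field(default_factory=lambda: np.ones(8))
    anchor: int = _INDEX["angle_accel"]

    def __post_init__(self):
        alpha = np.asarray(self.alpha, dtype=float)
        s = np.asarray(self.s, dtype=float)
        if alpha.shape != (8,) or s.shape != (8,):
            raise ValueError("alpha and s must be length-8 vectors")
        if np.any(alpha < 0):
            raise ValueError("weights must be non-negative")
        if not np.any(alpha > 0):
            raise ValueError("at least one weight must be positive")
        if np.any(s <= 0):
            raise ValueError("re-scaling factors must be positive")
        if not 0 <= self.anchor < 8:
            raise ValueError("anchor index out of range")
        self.alpha = alpha
        self.s = s

    @classmethod
    def single(cls, name: str, s: Optional[np.ndarray] = None) -> "CostWeights":
        """Pure single-cost weights (basis vector on the named cost)."""
        alpha = np.zeros(8)
        alpha[_INDEX[name]] = 1.0
        return cls(alpha=alpha, s=np.ones(8) if s is None else s,
                   anchor=_INDEX[name])

    @classmethod
    def hybrid(cls, ratio: float = 10.0, s: Optional[np.ndarray] = None) -> "CostWeights":
        """Energy + joint-smoothness composite with the given raw
        energy : angle-acceleration weight ratio (default 10:1)."""
        alpha = np.zeros(8)
        alpha[_INDEX["angle_accel"]] = 1.0
        alpha[_INDEX["energy"]] = ratio
        return cls(alpha=alpha, s=np.ones(8) if s is None else s)

    @property
    def normalized(self) -> np.ndarray:
        """Weights normalized to sum to one."""
        return self.alpha / self.alpha.sum()

    def names_nonzero(self):
        return [n for n, a in zip(BASIS_COSTS, self.alpha) if a > 0]


@dataclass
class Trajectory:
    """A sampled arm trajectory: time grid, joint states and fingertip
    kinematics.

    Fingertip fields are mandatory; joint/torque fields may be absent for
    purely kinematic (recorded or analytic end-point) trajectories, in
    which case only the hand-jerk cost and path metrics are defined.
    ``quad_w`` optionally carries quadrature weights native to the grid
    (e.g. Gauss weights); otherwise time integrals use the trapezoid rule.
    """

    t: np.ndarray
    pos: np.ndarray
    vel: Optional[np.ndarray] = None
    acc: Optional[np.ndarray] = None
    jerk: Optional[np.ndarray] = None
    q: Optional[np.ndarray] = None
    qdot: Optional[np.ndarray] = None
    qddot: Optional[np.ndarray] = None
    qdddot: Optional[np.ndarray] = None
    tau: Optional[np.ndarray] = None
    taudot: Optional[np.ndarray] = None
    u: Optional[np.ndarray] = None
    quad_w: Optional[np.ndarray] = None

    def __post_init__(self):
        self.t = np.asarray(self.t, dtype=float)
        if self.t.ndim != 1 or len(self.t) < 2:
            raise ValueError("time grid must be a 1-D array with >= 2 samples")
        if np.any(np.diff(self.t) <= 0):
            raise ValueError("time grid must be strictly increasing")
        self.pos = np.asarray(self.pos, dtype=float)
        if self.pos.shape != (len(self.t), 2):
            raise ValueError("pos must have shape (n, 2)")

    @property
    def n_samples(self) -> int:
        return len(self.t)

    @property
    def duration(self) -> float:
        return float(self.t[-1] - self.t[0])

    @property
    def speed(self) -> np.ndarray:
        if self.vel is None:
            raise ValueError("trajectory carries no velocity field")
        return np.linalg.norm(self.vel, axis=-1)

    def integrate(self, f: np.ndarray) -> float:
        """∫ f dt over the grid (Gauss weights if native, else trapezoid)."""
        if self.quad_w is not None:
            return float(self.quad_w @ f)
        return float(np.trapezoid(f, self.t))

    @classmethod
    def from_joint_profile(cls, t, q, qdot, qddot, qdddot, qddddot,
                           params: ArmParams, quad_w=None) -> "Trajectory":
        """Build the full trajectory from joint kinematics up to the 4th
        derivative, deriving torques and the neural command from the
        inverse dynamics and its time derivatives."""
        tau = inverse_dynamics(q, qdot, qddot, params)
        taud = torque_rate(q, qdot, qddot, qdddot, params)
        u = torque_accel(q, qdot, qddot, qdddot, qddddot, params)
        pos, vel, acc, jerk = fingertip_chain(q, qdot, qddot, qdddot, params=params)
        return cls(t=t, pos=pos, vel=vel, acc=acc, jerk=jerk,
                   q=q, qdot=qdot, qddot=qddot, qdddot=qdddot,
                   tau=tau, taudot=taud, u=u, quad_w=quad_w)

    def resample(self, n: int) -> "Trajectory":
        """Cubic-spline resampling to n uniformly spaced samples.

        Position-like fields are interpolated; velocity/acceleration/jerk
        of the fingertip are re-derived from the position spline so the
        output stays internally consistent.
        """
        t_new = np.linspace(self.t[0], self.t[-1], n)
        sp = CubicSpline(self.t, self.pos, axis=0)
        out = dict(t=t_new, pos=sp(t_new), vel=sp(t_new, 1), acc=sp(t_new, 2),
                   jerk=sp(t_new, 3))
        for name in ("q", "qdot", "qddot", "qdddot", "tau", "taudot", "u"):
            v = getattr(self, name)
            if v is not None:
                out[name] = CubicSpline(self.t, v, axis=0)(t_new)
        return Trajectory(**out)

    def time_reversed(self) -> "Trajectory":
        """The same path traversed backwards in time.

        Derivative fields flip sign according to their order.  The torque
        fields follow the parity of the conservative dynamics (τ even,
        τ̇ odd, u even), which is exact when the viscosity matrix is zero;
        with viscosity the reversed motion requires different torques and
        the torque fields should be recomputed via inverse dynamics.
        """
        def flip(v, sign):
            return None if v is None else sign * v[::-1]
        t_rev = self.t[-1] - self.t[::-1]
        return Trajectory(
            t=t_rev, pos=flip(self.pos, 1), vel=flip(self.vel, -1),
            acc=flip(self.acc, 1), jerk=flip(self.jerk, -1),
            q=flip(self.q, 1), qdot=flip(self.qdot, -1),
            qddot=flip(self.qddot, 1), qdddot=flip(self.qdddot, -1),
            tau=flip(self.tau, 1), taudot=flip(self.taudot, -1),
            u=flip(self.u, 1),
            quad_w=None if self.quad_w is None else self.quad_w[::-1],
        )


def _require(traj: Trajectory, *fields) -> None:
    for f in fields:
        if getattr(traj, f) is None:
            raise ValueError(
                f"trajectory lacks field {f!r} required by this cost"
            )


def basis_cost(traj: Trajectory, name: str, params: ArmParams,
               eps: float = 1e-6) -> float:
    """Evaluate one basis cost functional on a trajectory.

    eps regularizes the nonsmooth integrands (geodesic, energy) and is
    ignored by the quadratic costs.
    """
    if eps < 0:
        raise ValueError("eps must be >= 0")
    if name not in _INDEX:
        raise KeyError(f"unknown basis cost {name!r}; valid: {BASIS_COSTS}")
    if name == "hand_jerk":
        _require(traj, "jerk")
        f = np.sum(traj.jerk**2, axis=-1)
    elif name == "angle_jerk":
        _require(traj, "qdddot")
        f = np.sum(traj.qdddot**2, axis=-1)
    elif name == "angle_accel":
        _require(traj, "qddot")
        f = np.sum(traj.qddot**2, axis=-1)
    elif name == "torque_change":
        _require(traj, "taudot")
        f = np.sum(traj.taudot**2, axis=-1)
    elif name == "torque":
        _require(traj, "tau")
        f = np.sum(traj.tau**2, axis=-1)
    elif name == "geodesic":
        _require(traj, "q", "qdot")
        M = mass_matrix(traj.q, params)
        quad = np.einsum("ni,nij,nj->n", traj.qdot, M, traj.qdot)
        f = np.sqrt(quad + eps)
    elif name == "energy":
        _require(traj, "tau", "qdot")
        power = traj.tau * traj.qdot
        f = np.sum(np.sqrt(power**2 + eps**2), axis=-1)
    elif name == "effort":
        _require(traj, "u")
        f = np.sum(traj.u**2, axis=-1)
    return traj.integrate(f)


def all_basis_costs(traj: Trajectory, params: ArmParams,
                    eps: float = 1e-6) -> np.ndarray:
    """All eight basis costs as a vector in canonical order."""
    return np.array([basis_cost(traj, n, params, eps) for n in BASIS_COSTS])


def composite_cost(traj: Trajectory, weights: CostWeights, params: ArmParams,
                   eps: float = 1e-6) -> float:
    """Weighted composite Σᵢ αᵢ sᵢ Cᵢ(traj); only costs with αᵢ > 0 are
    evaluated, so trajectories may lack fields unused by the composite."""
    total = 0.0
    for i, name in enumerate(BASIS_COSTS):
        if weights.alpha[i] > 0:
            total += weights.alpha[i] * weights.s[i] * basis_cost(
                traj, name, params, eps)
    return total


def cost_contributions(basis_values: np.ndarray,
                       weights: CostWeights) -> np.ndarray:
    """Fractional contribution of each basis cost to the composite total.

    basis_values are the eight Cᵢ of a solution; the fractions
    αᵢsᵢCᵢ / ΣαⱼsⱼCⱼ sum to one.
    """
    basis_values = np.asarray(basis_values, dtype=float)
    terms = weights.alpha * weights.s * basis_values
    total = terms.sum()
    if total <= 0:
        raise ValueError("composite cost is zero; contributions undefined")
    return terms / total
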