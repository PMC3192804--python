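"""Direct optimal control of point-to-bar and point-to-point reaching.

The torque-actuated arm (u = τ̈) is differentially flat: the joint path
q(t) determines every state and the control through the inverse dynamics
and its time derivatives.  The solver therefore parametrizes each joint
angle directly,

    qᵢ(s) = q0ᵢ + (qTᵢ − q0ᵢ) h(s) + Σₖ cᵢₖ φₖ(s),      s = t/T,

with h the quintic smoothstep (h(0)=0, h(1)=1, h'=h''=0 at both ends) and
φₖ(s) = s³(1−s)³ Lₖ(2s−1) a modulated Legendre basis vanishing with its
first two derivatives at both ends.  Any coefficient vector then yields a
trajectory that satisfies the dynamics exactly and meets rest-to-rest
boundary conditions (q̇ = q̈ = 0, hence τ = G(q), at both ends; the torque
rate τ̇ is free at both ends, matching a terminal manifold that constrains
only velocity and acceleration).  The optimal control problem reduces to a
smooth finite-dimensional minimization over (c, z_f), where z_f is the
free endpoint height on the bar, solved by quasi-Newton descent with
batched finite-difference gradients and an eps-continuation schedule for
the nonsmooth cost ingredients.  Movement costs are integrated with
Gauss–Legendre quadrature at ``SolverOptions.nodes`` points.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from numpy.polynomial import legendre
import numpy.polynomial.polynomial as npoly
from scipy.optimize import minimize

from .arm_model import (
    ArmParams,
    fingertip_chain,
    forward_kinematics,
    gravity_vector,
    inverse_dynamics,
    inverse_kinematics,
    mass_matrix,
    torque_accel,
    torque_rate,
)
from .cost_functions import (
    BASIS_COSTS,
    CostWeights,
    Trajectory,
    all_basis_costs,
    cost_contributions,
)

__all__ = ["TaskSpec", "SolverOptions", "OCPSolution", "solve_ocp",
           "min_jerk_analytic", "endpoint_cost_profile", "EndpointProfile",
           "reachable_half_length"]

_NONSMOOTH = {"geodesic", "energy"}


# ---------------------------------------------------------------------------
# task and option containers


@dataclass(frozen=True)
class TaskSpec:
    """One reaching task: start posture, duration, and target.

    target is ("bar", d) — reach the vertical bar at antero-posterior
    distance d from the shoulder, endpoint height free — or
    ("point", (x, z)) — reach a fixed fingertip position.  The movement is
    rest-to-rest: zero velocity and zero acceleration at both ends.
    """

    q0: tuple
    T: float = 0.7
    target: tuple = ("bar", 0.65)
    label: str = ""

    def __post_init__(self):
        if self.T <= 0:
            raise ValueError("movement duration must be positive")
        kind = self.target[0]
        if kind not in ("bar", "point"):
            raise ValueError(f"unknown target kind {self.target[0]!r}")
        object.__setattr__(self, "q0", tuple(float(v) for v in self.q0))
        if kind == "bar":
            object.__setattr__(self, "target", ("bar", float(self.target[1])))
        else:
            object.__setattr__(
                self, "target",
                ("point", tuple(float(v) for v in self.target[1])))

    @property
    def is_bar(self) -> bool:
        return self.target[0] == "bar"

    def validate(self, params: ArmParams) -> None:
        if self.is_bar:
            d = self.target[1]
            if not 0 < d < params.L:
                raise ValueError(
                    f"bar distance {d:.3f} m outside the reachable range "
                    f"(0, {params.L:.3f}) m")
        else:
            inverse_kinematics(np.asarray(self.target[1]), params)

    def to_dict(self) -> dict:
        return {"q0": list(self.q0), "T": self.T, "label": self.label,
                "target": {"kind": self.target[0],
                           ("d" if self.is_bar else "p"):
                           self.target[1] if self.is_bar
                           else list(self.target[1])}}

    @classmethod
    def from_dict(cls, d: dict) -> "TaskSpec":
        tg = d["target"]
        target = ("bar", tg["d"]) if tg["kind"] == "bar" else \
            ("point", tuple(tg["p"]))
        return cls(q0=tuple(d["q0"]), T=d["T"], target=target,
                   label=d.get("label", ""))


@dataclass
class SolverOptions:
    """Numerical options of the direct solver."""

    nodes: int = 40  # Gauss-Legendre quadrature points
    basis_size: int = 8  # free basis functions per joint
    eps_schedule: tuple = (1e-2, 1e-4, 1e-6)  # smoothing continuation
    maxiter: int = 700  # quasi-Newton iterations per continuation stage
    ftol: float = 1e-12
    gtol: float = 1e-9
    n_starts: int = 3  # multi-start attempts when the first solve fails
    seed: int = 0
    n_out: int = 201  # samples of the returned trajectory
    coeff_bound: float = 30.0  # |c| bound on basis coefficients (rad)
    penalty_weight: float = 1e3  # soft joint-limit / control-bound penalty

    def __post_init__(self):
        if self.nodes < 10:
            raise ValueError("need at least 10 quadrature nodes")
        if self.basis_size < 1:
            raise ValueError("basis_size must be >= 1")


@dataclass
class OCPSolution:
    """Result of one direct OCP solve."""

    trajectory: Trajectory
    total_cost: float
    basis_costs: dict
    contributions: Optional[dict]
    weights: CostWeights
    task: TaskSpec
    residuals: dict
    status: str
    diagnostics: dict
    theta: np.ndarray  # internal decision vector, reusable as warm start

    @property
    def z_f(self) -> float:
        """Endpoint height of the fingertip (m)."""
        return float(self.trajectory.pos[-1, 1])

    def to_dict(self) -> dict:
        return {
            "task": self.task.to_dict(),
            "weights": {"alpha": self.weights.alpha.tolist(),
                        "s": self.weights.s.tolist()},
            "total_cost": self.total_cost,
            "basis_costs": self.basis_costs,
            "contributions": self.contributions,
            "z_f": self.z_f,
            "residuals": self.residuals,
            "status": self.status,
            "diagnostics": {k: v for k, v in self.diagnostics.items()
                            if np.isscalar(v) or isinstance(v, str)},
        }


# ---------------------------------------------------------------------------
# trajectory basis


def _smoothstep_derivs(s: np.ndarray) -> list:
    """Quintic smoothstep h(s)=10s³−15s⁴+6s⁵ and d^r h/ds^r, r=0..4."""
    coef = np.array([0, 0, 0, 10.0, -15.0, 6.0])
    out = []
    for r in range(5):
        out.append(npoly.polyval(s, npoly.polyder(coef, r) if r else coef))
    return out


def _basis_derivs(s: np.ndarray, K: int) -> list:
    """φₖ(s) = s³(1−s)³ Lₖ(2s−1) and derivatives to order 4.

    Returns a list of five (len(s), K) arrays.  Leibniz rule over the
    window polynomial w(s) (exact polynomial derivatives) and the shifted
    Legendre factor (chain rule gives a factor 2 per derivative).
    """
    w = npoly.polymul(np.array([0, 0, 0, 1.0]),  # s^3
                      npoly.polymul(npoly.polymul([1.0, -1.0], [1.0, -1.0]),
                                    [1.0, -1.0]))  # (1-s)^3
    wd = [npoly.polyval(s, npoly.polyder(w, r) if r else w) for r in range(5)]
    x = 2.0 * s - 1.0
    L = np.zeros((5, len(s), K))
    for k in range(K):
        e = np.zeros(k + 1)
        e[k] = 1.0
        c = e
        for r in range(5):
            L[r, :, k] = (2.0**r) * legendre.legval(x, c)
            c = legendre.legder(c) if len(c) > 1 else np.zeros(1)
    from math import comb
    out = []
    for r in range(5):
        phi_r = np.zeros((len(s), K))
        for i in range(r + 1):
            phi_r += comb(r, i) * wd[i][:, None] * L[r - i]
        out.append(phi_r)
    return out


class _Transcription:
    """Precomputed basis/quadrature data for one (task, options) pair."""

    def __init__(self, task: TaskSpec, params: ArmParams,
                 options: SolverOptions):
        self.task, self.params, self.options = task, params, options
        K = options.basis_size
        x_gl, w_gl = legendre.leggauss(options.nodes)
        self.s_nodes = 0.5 * (x_gl + 1.0)
        self.w_nodes = 0.5 * w_gl  # weights on [0, 1]
        self.h_nodes = _smoothstep_derivs(self.s_nodes)
        self.phi_nodes = _basis_derivs(self.s_nodes, K)
        s_out = np.linspace(0.0, 1.0, options.n_out)
        self.h_out = _smoothstep_derivs(s_out)
        self.phi_out = _basis_derivs(s_out, K)
        self.s_out = s_out
        self.q0 = np.asarray(task.q0, dtype=float)
        self.K = K
        self.n_free = 2 * K + (1 if task.is_bar else 0)
        if task.is_bar:
            d = task.target[1]
            self.z_half = reachable_half_length(d, params)
        else:
            self.qT_fixed = inverse_kinematics(
                np.asarray(task.target[1]), params)

    # --- decision vector layout: [c1 (K), c2 (K), (z_f)] ------------------
    def split(self, theta: np.ndarray):
        K = self.K
        c = np.stack([theta[..., :K], theta[..., K:2 * K]], axis=-1)  # (...,K,2)
        z_f = theta[..., 2 * K] if self.task.is_bar else None
        return c, z_f

    def terminal_q(self, z_f):
        if self.task.is_bar:
            d = self.task.target[1]
            p = np.stack([np.broadcast_to(d, np.shape(z_f)),
                          np.asarray(z_f)], axis=-1)
            return inverse_kinematics(p, self.params)
        return self.qT_fixed

    def joint_profile(self, theta: np.ndarray, at_output: bool = False):
        """Joint kinematics q, q̇, q̈, q⃛, q⁗ at the node set.

        theta may be a batch (m, n_free); outputs then gain a leading batch
        axis.  Time derivatives include the 1/T^r scaling.
        """
        h = self.h_out if at_output else self.h_nodes
        phi = self.phi_out if at_output else self.phi_nodes
        T = self.task.T
        c, z_f = self.split(theta)
        qT = self.terminal_q(z_f)  # (..., 2)
        dq = qT - self.q0
        out = []
        for r in range(5):
            # (..., n, 2): boundary interpolant + basis part, /T^r
            base = dq[..., None, :] * h[r][:, None]
            if r == 0:
                base = base + self.q0
            mod = np.einsum("nk,...ki->...ni", phi[r], c)
            out.append((base + mod) / T**r)
        return out

    def bounds(self):
        cb = self.options.coeff_bound
        b = [(-cb, cb)] * (2 * self.K)
        if self.task.is_bar:
            margin = 1e-3 * self.params.L
            b.append((-self.z_half + margin, self.z_half - margin))
        return b

    def initial_theta(self) -> np.ndarray:
        theta = np.zeros(self.n_free)
        if self.task.is_bar:
            z0 = forward_kinematics(self.q0, self.params)[1]
            lo, hi = self.bounds()[-1]
            theta[-1] = np.clip(z0, lo, hi)
        return theta


def reachable_half_length(d: float, params: ArmParams) -> float:
    """Half-length of the reachable region on a bar at distance d: the bar
    intersects the shoulder-centred circle of radius L at z = ±√(L²−d²)."""
    if not 0 < d < params.L:
        raise ValueError("bar beyond reach")
    return float(np.sqrt(params.L**2 - d**2))


# ---------------------------------------------------------------------------
# batched cost evaluation


def _batched_cost(tr: _Transcription, theta_batch: np.ndarray,
                  weights: CostWeights, eps: float) -> np.ndarray:
    """Composite cost (plus soft feasibility penalties) for a batch of
    decision vectors, vectorized over the batch and node axes."""
    p = tr.params
    T = tr.task.T
    q, qd, qdd, qddd, qdddd = tr.joint_profile(theta_batch)
    alpha_s = weights.alpha * weights.s
    need_tau = np.any(alpha_s[[3, 4, 6, 7]] > 0)
    f = 0.0
    if alpha_s[0] > 0:  # hand jerk
        _, _, _, jerk = fingertip_chain(q, qd, qdd, qddd, params=p)
        f = f + alpha_s[0] * np.sum(jerk**2, axis=-1)
    if alpha_s[1] > 0:  # angle jerk
        f = f + alpha_s[1] * np.sum(qddd**2, axis=-1)
    if alpha_s[2] > 0:  # angle acceleration
        f = f + alpha_s[2] * np.sum(qdd**2, axis=-1)
    if need_tau:
        tau = inverse_dynamics(q, qd, qdd, p)
    if alpha_s[3] > 0:  # torque change
        taud = torque_rate(q, qd, qdd, qddd, p)
        f = f + alpha_s[3] * np.sum(taud**2, axis=-1)
    if alpha_s[4] > 0:  # torque
        f = f + alpha_s[4] * np.sum(tau**2, axis=-1)
    if alpha_s[5] > 0:  # geodesic
        M = mass_matrix(q, p)
        quad = np.einsum("...i,...ij,...j->...", qd, M, qd)
        f = f + alpha_s[5] * np.sqrt(quad + eps)
    if alpha_s[6] > 0:  # absolute work
        power = tau * qd
        f = f + alpha_s[6] * np.sum(np.sqrt(power**2 + eps**2), axis=-1)
    u = None
    if alpha_s[7] > 0:  # effort
        u = torque_accel(q, qd, qdd, qddd, qdddd, p)
        f = f + alpha_s[7] * np.sum(u**2, axis=-1)
    # soft biological-plausibility penalties (joint limits, command bound)
    if tr.options.penalty_weight > 0:
        pen = (np.maximum(q - np.asarray(p.q_max), 0.0)**2
               + np.maximum(np.asarray(p.q_min) - q, 0.0)**2).sum(axis=-1)
        if u is None:
            u = torque_accel(q, qd, qdd, qddd, qdddd, p)
        pen = pen + (np.maximum(np.abs(u) - p.u_max, 0.0)**2
                     ).sum(axis=-1) / p.u_max
        f = f + tr.options.penalty_weight * pen
    return T * (f @ tr.w_nodes)


def _make_objective(tr: _Transcription, weights: CostWeights, eps: float):
    h_fd = 1e-7

    def fun(theta):
        return float(_batched_cost(tr, theta[None, :], weights, eps)[0])

    def jac(theta):
        # one batched evaluation: base point + one forward step per dim
        D = len(theta)
        steps = h_fd * (1.0 + np.abs(theta))
        batch = np.concatenate([theta[None, :],
                                theta[None, :] + np.diag(steps)], axis=0)
        vals = _batched_cost(tr, batch, weights, eps)
        return (vals[1:] - vals[0]) / steps

    return fun, jac


# ---------------------------------------------------------------------------
# solver


def solve_ocp(task: TaskSpec, weights: CostWeights, params: ArmParams,
              options: Optional[SolverOptions] = None,
              x0: Optional[np.ndarray] = None) -> OCPSolution:
    """Solve the fixed-duration reaching OCP for the given composite cost.

    Returns the optimal trajectory sampled on a uniform grid, the
    per-basis cost values and their fractional contributions, terminal
    residuals and solver diagnostics.  ``x0`` warm-starts the decision
    vector (e.g. from a neighbouring solve).

    The transcription satisfies the dynamics and rest boundary conditions
    by construction, so the only residuals to report are the terminal
    kinematic ones (machine-precision except for the soft-penalized joint
    limits).
    """
    options = options or SolverOptions()
    task.validate(params)
    tr = _Transcription(task, params, options)
    nonsmooth = any(weights.alpha[BASIS_COSTS.index(n)] > 0
                    for n in _NONSMOOTH)
    schedule = tuple(options.eps_schedule) if nonsmooth else \
        (options.eps_schedule[-1],)
    bounds = tr.bounds()
    rng = np.random.default_rng(options.seed)

    def run_from(theta0):
        theta, res, ok = theta0, None, False
        for eps in schedule:
            fun, jac = _make_objective(tr, weights, eps)
            res = minimize(fun, theta, jac=jac, method="L-BFGS-B",
                           bounds=bounds,
                           options=dict(maxiter=options.maxiter,
                                        ftol=options.ftol,
                                        gtol=options.gtol))
            theta = res.x
            # A line-search stall (ABNORMAL) right after a converged
            # continuation stage means the FD gradient has reached its
            # noise floor at the sharpened kinks: accept as converged.
            stalled = "ABNORMAL" in str(res.message)
            ok = res.success or (ok and stalled)
        return theta, res, ok

    starts = [tr.initial_theta() if x0 is None
              else np.asarray(x0, dtype=float)]
    best_theta, best_res, best_ok = run_from(starts[0])
    attempts = 1
    while not best_ok and attempts < options.n_starts:
        pert = starts[0] + rng.normal(0.0, 0.2, size=tr.n_free)
        pert = np.clip(pert, [b[0] for b in bounds], [b[1] for b in bounds])
        theta, res, ok = run_from(pert)
        if (ok and not best_ok) or (ok == best_ok and res.fun < best_res.fun):
            best_theta, best_res, best_ok = theta, res, ok
        attempts += 1

    # assemble the solution on the output grid
    t_out = tr.s_out * task.T
    q, qd, qdd, qddd, qdddd = tr.joint_profile(best_theta, at_output=True)
    traj = Trajectory.from_joint_profile(t_out, q, qd, qdd, qddd, qdddd,
                                         params)
    eps_final = schedule[-1]
    basis_vals = all_basis_costs(traj, params, eps=eps_final)
    total = float(np.sum(weights.alpha * weights.s * basis_vals))
    try:
        contrib = cost_contributions(basis_vals, weights)
        contrib_d = dict(zip(BASIS_COSTS, contrib.tolist()))
    except ValueError:
        contrib_d = None
    p_T = traj.pos[-1]
    residuals = {
        "terminal_speed": float(np.linalg.norm(traj.vel[-1])),
        "terminal_accel": float(np.linalg.norm(traj.acc[-1])),
        "torque_rest": float(np.linalg.norm(
            traj.tau[-1] - gravity_vector(traj.q[-1], params))),
    }
    if task.is_bar:
        residuals["bar_distance"] = float(abs(p_T[0] - task.target[1]))
    else:
        residuals["target_distance"] = float(
            np.linalg.norm(p_T - np.asarray(task.target[1])))
    status = "success" if best_ok else \
        f"not_converged: {best_res.message}"
    diagnostics = {"nit": int(best_res.nit), "nfev": int(best_res.nfev),
                   "fun": float(best_res.fun), "message": str(best_res.message),
                   "n_starts_used": attempts,
                   "grad_norm": float(np.linalg.norm(np.atleast_1d(best_res.jac)))}
    return OCPSolution(trajectory=traj, total_cost=total,
                       basis_costs=dict(zip(BASIS_COSTS, basis_vals.tolist())),
                       contributions=contrib_d, weights=weights, task=task,
                       residuals=residuals, status=status,
                       diagnostics=diagnostics, theta=best_theta)


# ---------------------------------------------------------------------------
# analytic oracle


def min_jerk_analytic(p0, pf, T: float, n_samples: int = 201) -> Trajectory:
    """The minimum hand-jerk point-to-point trajectory in closed form.

    Each Cartesian coordinate follows the quintic
    p0 + (pf−p0)(10s³−15s⁴+6s⁵), s = t/T — a straight path with a
    bell-shaped speed profile whose peak/mean ratio is 15/8 = 1.875 and
    whose jerk cost is 720‖pf−p0‖²/T⁵.  Returns a fingertip-level
    trajectory (no joint or torque fields).
    """
    if T <= 0:
        raise ValueError("duration must be positive")
    p0 = np.asarray(p0, dtype=float)
    pf = np.asarray(pf, dtype=float)
    t = np.linspace(0.0, T, n_samples)
    s = t / T
    h, h1, h2, h3, _ = _smoothstep_derivs(s)
    dp = pf - p0
    return Trajectory(
        t=t,
        pos=p0 + dp[None, :] * h[:, None],
        vel=dp[None, :] * h1[:, None] / T,
        acc=dp[None, :] * h2[:, None] / T**2,
        jerk=dp[None, :] * h3[:, None] / T**3,
    )


# ---------------------------------------------------------------------------
# endpoint cost sweep along the bar


@dataclass
class EndpointProfile:
    """Optimal point-to-point cost as a function of the endpoint height on
    the bar, with the sub-optimality region below a relative threshold."""

    z: np.ndarray
    cost: np.ndarray  # NaN where the individual solve failed
    ok: np.ndarray  # bool flags per grid point
    threshold: float
    solutions: list

    @property
    def z_min(self) -> float:
        i = np.nanargmin(self.cost)
        return float(self.z[i])

    @property
    def min_cost(self) -> float:
        return float(np.nanmin(self.cost))

    def below_threshold(self) -> np.ndarray:
        """Endpoint heights whose cost is within (1+threshold)·min cost."""
        lim = (1.0 + self.threshold) * self.min_cost
        return self.z[np.where(np.nan_to_num(self.cost, nan=np.inf) <= lim)]


def endpoint_cost_profile(task: TaskSpec, weights: CostWeights,
                          params: ArmParams, spacing: float = 0.03,
                          options: Optional[SolverOptions] = None,
                          threshold: float = 0.10) -> EndpointProfile:
    """Sweep fixed-endpoint OCPs over the reachable region of the bar.

    The reachable region is the segment of the bar inside the
    shoulder-centred circle of radius L, discretized every ``spacing``
    metres; one point-to-point OCP is solved per grid point (warm-started
    from its neighbour).  Individual failures are recorded and leave gaps.
    """
    if spacing <= 0:
        raise ValueError("spacing must be positive")
    if not task.is_bar:
        raise ValueError("endpoint_cost_profile requires a bar task")
    options = options or SolverOptions()
    d = task.target[1]
    zh = reachable_half_length(d, params)
    margin = 2e-3 * params.L
    z_grid = np.arange(-zh + margin, zh - margin + 1e-12, spacing)
    costs = np.full(len(z_grid), np.nan)
    ok = np.zeros(len(z_grid), dtype=bool)
    sols: list = []
    warm = None
    for j, z in enumerate(z_grid):
        sub = TaskSpec(q0=task.q0, T=task.T, target=("point", (d, z)),
                       label=f"{task.label}:z={z:.3f}")
        try:
            sol = solve_ocp(sub, weights, params, options, x0=warm)
            costs[j] = sol.total_cost
            ok[j] = sol.status == "success"
            warm = sol.theta
            sols.append(sol)
        except Exception:  # keep sweeping; gap stays NaN
            sols.append(None)
            warm = None
    return EndpointProfile(z=z_grid, cost=costs, ok=ok, threshold=threshold,
                           solutions=sols)
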