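"""Bi-level inverse optimal control: recover cost weights from trajectories.

The outer loop searches the non-negative weight vector α (one component
anchored to 1, by convention the angle-acceleration weight, since scaling
all weights leaves the optimal trajectories unchanged); the inner loop
solves one direct OCP per observed posture and scores the mismatch

    Φ(α) = Σ_postures  metric( x_α , x_obs ),

with a path metric combining the mean Cartesian fingertip distance and
the difference in signed path curvature.  Because each Φ evaluation is an
approximate inner optimum, Φ is treated as noisy and non-differentiable:
the outer minimization uses a bound-constrained derivative-free
trust-region method with quadratic local models (COBYQA), restarted from
several initial guesses.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import minimize

from .arm_model import ArmParams, forward_kinematics
from .cost_functions import BASIS_COSTS, CostWeights, Trajectory, \
    cost_contributions
from .direct_ocp import SolverOptions, TaskSpec, solve_ocp
from .kinematic_analysis import N_NORMALIZED, signed_path_curvature
from .synthetic_data import ObservationSet

__all__ = ["InverseConfig", "InverseResult", "trajectory_metric",
           "cartesian_errors", "compute_rescaling", "fit_weights"]


@dataclass
class InverseConfig:
    """Configuration of the outer (weight-space) search."""

    anchor: int = BASIS_COSTS.index("angle_accel")  # weight fixed to 1
    bound: float = 30.0  # upper bound on each free weight
    budget: int = 150  # max inner OCP solves per restart
    restarts: int = 3  # one all-ones start + restarts-1 random starts
    lambda_c: float = 1.0  # weight of the curvature term in the metric
    seed: int = 0
    s: Optional[np.ndarray] = None  # re-scaling vector; computed if None
    final_tr_radius: float = 1e-3  # trust-region floor (scaled weight units)
    polish: bool = True  # sparsify path-equivalent weights (Occam tie-break)
    polish_rtol: float = 0.02  # max relative Phi increase accepted when zeroing

    def __post_init__(self):
        if self.budget < 1:
            raise ValueError("budget must be >= 1")
        if self.lambda_c < 0:
            raise ValueError("lambda_c must be >= 0")
        if not 0 <= self.anchor < 8:
            raise ValueError("anchor index out of range")


@dataclass
class InverseResult:
    """Outcome of one weight-recovery run."""

    weights: CostWeights  # fitted weights (anchor = 1 convention)
    phi: float  # fitting error, recomputed from scratch at the optimum
    phi_per_posture: dict
    contributions: dict  # mean fractional cost contributions
    cartesian_error_mean: float  # mean fingertip distance (m), all postures
    cartesian_error_max: float  # max fingertip distance (m), all postures
    trace: list  # best-so-far Φ per outer iteration, all restarts
    best_restart: int
    n_inner_solves: int
    flags: list = field(default_factory=list)

    @property
    def normalized_weights(self) -> np.ndarray:
        return self.weights.normalized

    def to_dict(self) -> dict:
        return {
            "alpha": self.weights.alpha.tolist(),
            "alpha_normalized": self.normalized_weights.tolist(),
            "s": self.weights.s.tolist(),
            "anchor": int(self.weights.anchor),
            "phi": self.phi,
            "phi_per_posture": self.phi_per_posture,
            "contributions": self.contributions,
            "cartesian_error_mean": self.cartesian_error_mean,
            "cartesian_error_max": self.cartesian_error_max,
            "best_restart": self.best_restart,
            "n_inner_solves": self.n_inner_solves,
            "flags": self.flags,
        }


# ---------------------------------------------------------------------------
# the trajectory metric


def _chord_length(traj: Trajectory) -> float:
    return float(np.linalg.norm(traj.pos[-1] - traj.pos[0]))


def trajectory_metric(sim: Trajectory, ref: Trajectory,
                      lambda_c: float = 1.0) -> float:
    """Cartesian + curvature mismatch between two time-normalized paths.

    metric = mean_n ‖p_sim(n) − p_ref(n)‖
             + λc · |sIPC(sim) − sIPC(ref)| · chord_length(ref).

    Both trajectories must share the same normalized sample count; the
    curvature term is scaled by the reference chord so both terms are in
    metres.  Zero iff the sampled paths coincide and curvatures match.
    """
    if sim.n_samples != ref.n_samples:
        raise ValueError(
            f"trajectories sampled on different grids ({sim.n_samples} vs "
            f"{ref.n_samples}); resample to a common normalized grid first")
    cart = float(np.mean(np.linalg.norm(sim.pos - ref.pos, axis=1)))
    if lambda_c == 0:
        return cart
    curv = abs(signed_path_curvature(sim.pos) - signed_path_curvature(ref.pos))
    return cart + lambda_c * curv * _chord_length(ref)


def cartesian_errors(sim: Trajectory, ref: Trajectory) -> tuple:
    """(mean, max) sample-wise fingertip distance between two paths (m)."""
    if sim.n_samples != ref.n_samples:
        raise ValueError("trajectories sampled on different grids")
    dist = np.linalg.norm(sim.pos - ref.pos, axis=1)
    return float(dist.mean()), float(dist.max())


# ---------------------------------------------------------------------------
# re-scaling vector


def compute_rescaling(tasks: Sequence[TaskSpec], params: ArmParams,
                      options: Optional[SolverOptions] = None) -> np.ndarray:
    """Re-scaling factors sᵢ = 1 / median optimal single-cost value.

    Each basis cost is minimized alone on point-to-point versions of the
    given tasks (bar targets are pinned at the start height); the median
    optimal value over tasks calibrates that cost's magnitude, so that
    after re-scaling single-cost optima are O(1).
    """
    if not tasks:
        raise ValueError("need at least one task")
    options = options or SolverOptions()
    s = np.empty(8)
    for i, name in enumerate(BASIS_COSTS):
        vals = []
        for task in tasks:
            if task.is_bar:
                d = task.target[1]
                z0 = forward_kinematics(np.asarray(task.q0), params)[1]
                zh = np.sqrt(params.L**2 - d**2)
                z0 = float(np.clip(z0, -zh + 2e-3, zh - 2e-3))
                sub = TaskSpec(q0=task.q0, T=task.T, target=("point", (d, z0)),
                               label=task.label)
            else:
                sub = task
            try:
                sol = solve_ocp(sub, CostWeights.single(name), params, options)
                if sol.total_cost > 0 and np.isfinite(sol.total_cost):
                    vals.append(sol.total_cost)
            except Exception:
                continue
        if not vals:
            raise RuntimeError(
                f"single-cost solves failed on every task for {name!r}")
        s[i] = 1.0 / float(np.median(vals))
    return s


# ---------------------------------------------------------------------------
# the bi-level fit


def _insert_anchor(y: np.ndarray, anchor: int) -> np.ndarray:
    alpha = np.empty(8)
    alpha[:anchor] = y[:anchor]
    alpha[anchor] = 1.0
    alpha[anchor + 1:] = y[anchor:]
    return np.maximum(alpha, 0.0)


def fit_weights(obs: ObservationSet, config: InverseConfig,
                params: ArmParams,
                options: Optional[SolverOptions] = None) -> InverseResult:
    """Recover the cost-weight vector explaining an observation set.

    Runs a bound-constrained derivative-free trust-region search over the
    seven free weights (anchor fixed at 1), with inner OCP solves
    warm-started from neighbouring outer iterates, restarted
    ``config.restarts`` times (all-ones plus random non-negative starts).
    The reported Φ is recomputed from scratch (no warm start) at the
    returned weights.
    """
    if not obs.postures:
        raise ValueError("observation set is empty")
    options = options or SolverOptions()
    s = config.s
    if s is None:
        s = compute_rescaling([po.task for po in obs.postures.values()],
                              params, options)
    s = np.asarray(s, dtype=float)
    refs = {}
    for label, po in obs.postures.items():
        ref = po.reference
        if ref.n_samples != N_NORMALIZED:
            ref = ref.resample(N_NORMALIZED)
        refs[label] = ref

    rng = np.random.default_rng(config.seed)
    n_postures = len(obs.postures)
    maxfev = max(2 * 7 + 1, config.budget // n_postures)
    counter = {"solves": 0}
    trace: list = []

    def make_phi(warm: dict):
        def phi(y):
            alpha = _insert_anchor(np.asarray(y, dtype=float), config.anchor)
            try:
                weights = CostWeights(alpha=alpha, s=s, anchor=config.anchor)
            except ValueError:
                return 1e6
            total = 0.0
            for label, po in obs.postures.items():
                sol = solve_ocp(po.task, weights, params, options,
                                x0=warm.get(label))
                warm[label] = sol.theta
                counter["solves"] += 1
                sim = sol.trajectory.resample(N_NORMALIZED)
                total += trajectory_metric(sim, refs[label], config.lambda_c)
            best = min(trace[-1], total) if trace else total
            trace.append(best)
            return total
        return phi

    bounds = [(0.0, config.bound)] * 7
    starts = [np.ones(7)]
    for _ in range(max(0, config.restarts - 1)):
        starts.append(rng.uniform(0.0, 2.0, size=7))

    best_y, best_phi, best_restart, budget_hit = None, np.inf, -1, False
    for r, y0 in enumerate(starts):
        warm: dict = {}
        phi = make_phi(warm)
        res = minimize(phi, y0, method="cobyqa", bounds=bounds,
                       options=dict(maxfev=maxfev,
                                    final_tr_radius=config.final_tr_radius))
        if res.fun < best_phi:
            best_y, best_phi, best_restart = np.asarray(res.x), float(res.fun), r
        if res.nfev >= maxfev:
            budget_hit = True
    if best_y is None:
        raise RuntimeError("every restart failed to produce a feasible fit")

    if config.polish and np.any(best_y > 0):
        # Sparsification pass: weight vectors differing only in components
        # whose removal leaves Φ unchanged (within inner-solver noise) are
        # path-equivalent; prefer the sparser one.  Components are tried in
        # ascending order of magnitude and zeroed when Φ does not worsen
        # beyond the accepted tolerance.
        warm: dict = {}
        phi = make_phi(warm)
        phi_best = phi(best_y)
        tol = phi_best * config.polish_rtol + 1e-5
        for idx in np.argsort(best_y):
            if best_y[idx] <= 0:
                continue
            trial = best_y.copy()
            trial[idx] = 0.0
            phi_trial = phi(trial)
            if phi_trial <= phi_best + tol:
                best_y, phi_best = trial, min(phi_best, phi_trial)

    # from-scratch re-evaluation at the fitted weights
    alpha = _insert_anchor(best_y, config.anchor)
    weights = CostWeights(alpha=alpha, s=s, anchor=config.anchor)
    phi_pp, contribs, cart_means, cart_maxes = {}, [], [], []
    for label, po in obs.postures.items():
        sol = solve_ocp(po.task, weights, params, options)
        counter["solves"] += 1
        sim = sol.trajectory.resample(N_NORMALIZED)
        phi_pp[label] = trajectory_metric(sim, refs[label], config.lambda_c)
        cm, cx = cartesian_errors(sim, refs[label])
        cart_means.append(cm)
        cart_maxes.append(cx)
        basis_vals = np.array([sol.basis_costs[n] for n in BASIS_COSTS])
        contribs.append(cost_contributions(basis_vals, weights))
    phi_total = float(sum(phi_pp.values()))
    flags = []
    if budget_hit:
        flags.append("budget_exhausted: best-so-far returned")
    if np.any(best_y >= 0.95 * config.bound):
        flags.append("free weight at upper bound: the anchored component "
                     "may be absent from the true cost")
    return InverseResult(
        weights=weights, phi=phi_total, phi_per_posture=phi_pp,
        contributions=dict(zip(BASIS_COSTS,
                               np.mean(contribs, axis=0).tolist())),
        cartesian_error_mean=float(np.mean(cart_means)),
        cartesian_error_max=float(np.max(cart_maxes)),
        trace=trace, best_restart=best_restart,
        n_inner_solves=counter["solves"], flags=flags)
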