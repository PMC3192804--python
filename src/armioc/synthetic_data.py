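"""Synthetic observation sets with the statistical structure of
point-to-bar reaching recordings.

Each simulated subject performs rest-to-rest reaches from five starting
postures toward a vertical bar placed at 85% of arm length, sampled at
100 Hz, with bell-shaped speed profiles.  Trial-to-trial variability
follows the empirically observed pattern: endpoint scatter along the bar
(vertical SD about three times the antero-posterior SD), smooth
within-trial path perturbations, and duration jitter.  Ground-truth cost
weights are recorded alongside so the inverse procedure can be validated
end to end.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy.interpolate import CubicSpline

from .arm_model import ArmParams, forward_kinematics, inverse_kinematics
from .cost_functions import CostWeights, Trajectory
from .direct_ocp import (
    SolverOptions,
    TaskSpec,
    reachable_half_length,
    solve_ocp,
)
from . import kinematic_analysis as ka

__all__ = ["NoiseModel", "PostureObservation", "ObservationSet",
           "default_tasks", "generate_observations", "simulate_protocol",
           "save_observations", "load_observations"]

SAMPLING_HZ = 100.0

# Five rest postures spanning start points below, level with and above the
# shoulder (fingertip heights about -0.36L to +0.40L), all inside the
# default joint limits.
DEFAULT_POSTURES = (
    ("P1", (-1.450, 1.550)),
    ("P2", (-1.421, 1.900)),
    ("P3", (-1.344, 2.269)),
    ("P4", (-0.884, 1.962)),
    ("P5", (-0.424, 1.962)),
)


@dataclass(frozen=True)
class NoiseModel:
    """Trial-to-trial variability of the synthetic recordings (SI units)."""

    endpoint_sd_z: float = 0.03  # vertical scatter of endpoints on the bar (m)
    endpoint_sd_x: float = 0.01  # antero-posterior endpoint error (m)
    kinematic_sd: float = 0.005  # smooth within-trial path perturbation (m)
    duration_cv: float = 0.1  # trial-to-trial duration variability
    seed: int = 0

    def __post_init__(self):
        for name in ("endpoint_sd_z", "endpoint_sd_x", "kinematic_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0 <= self.duration_cv < 0.5:
            raise ValueError("duration_cv must be in [0, 0.5)")

    @property
    def silent(self) -> bool:
        return (self.endpoint_sd_z == 0 and self.endpoint_sd_x == 0
                and self.kinematic_sd == 0 and self.duration_cv == 0)


@dataclass
class PostureObservation:
    task: TaskSpec
    reference: Trajectory  # trial-averaged, time-normalized (200 samples)
    trials: list = field(default_factory=list)


@dataclass
class ObservationSet:
    postures: dict  # label -> PostureObservation
    ground_truth: dict = field(default_factory=dict)

    def labels(self):
        return list(self.postures)

    def __len__(self):
        return len(self.postures)


def default_tasks(params: ArmParams, d_frac: float = 0.85,
                  T: float = 0.7, postures=DEFAULT_POSTURES) -> list:
    """The study's task set: one bar-reaching task per starting posture,
    bar at ``d_frac`` of arm length, fixed movement duration."""
    d = d_frac * params.L
    return [TaskSpec(q0=q0, T=T, target=("bar", d), label=label)
            for label, q0 in postures]


def _trial_from_joint_path(t: np.ndarray, q: np.ndarray,
                           params: ArmParams) -> Trajectory:
    """Recorded-trial-like trajectory: positions from the joint path, with
    velocity and higher derivatives from a position spline (as they would
    be obtained from motion capture)."""
    pos = forward_kinematics(q, params)
    sp = CubicSpline(t, pos, axis=0)
    spq = CubicSpline(t, q, axis=0)
    return Trajectory(t=t, pos=pos, vel=sp(t, 1), acc=sp(t, 2),
                      jerk=sp(t, 3), q=q, qdot=spq(t, 1))


def _average_reference(trials: Sequence[Trajectory],
                       params: ArmParams) -> Trajectory:
    """Trial-averaged, time-normalized reference trajectory."""
    n = ka.N_NORMALIZED
    q_stack = []
    durations = []
    for tr in trials:
        s = (tr.t - tr.t[0]) / tr.duration
        q_stack.append(CubicSpline(s, tr.q, axis=0)(np.linspace(0, 1, n)))
        durations.append(tr.duration)
    q_mean = np.mean(q_stack, axis=0)
    T_mean = float(np.mean(durations))
    t = np.linspace(0.0, T_mean, n)
    return _trial_from_joint_path(t, q_mean, params)


def generate_observations(true_weights: CostWeights, tasks: Sequence[TaskSpec],
                          noise: NoiseModel, n_trials: int,
                          params: ArmParams,
                          options: Optional[SolverOptions] = None,
                          resolve: bool = True) -> ObservationSet:
    """Simulate a subject's recording session under known cost weights.

    Per task the nominal bar OCP is solved; each trial jitters the
    endpoint on the bar (vertical and antero-posterior noise), then either
    re-solves the fixed-endpoint OCP (``resolve=True``) or warps the
    nominal joint path toward the jittered endpoint, adds smooth
    sine-half-wave joint perturbations vanishing at both ends, and scales
    the duration.  Returns the trials, the trial-averaged 200-sample
    reference per posture, and the ground-truth record.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    options = options or SolverOptions()
    rng = np.random.default_rng(noise.seed)
    postures = {}
    for task in tasks:
        nominal = solve_ocp(task, true_weights, params, options)
        if nominal.status != "success":
            raise RuntimeError(
                f"nominal OCP failed for task {task.label!r}: "
                f"{nominal.status} (diagnostics: {nominal.diagnostics})")
        d = task.target[1] if task.is_bar else nominal.trajectory.pos[-1, 0]
        z_nom = nominal.z_f
        zh = reachable_half_length(d, params) if task.is_bar else None
        trials = []
        warm = None
        for _ in range(n_trials):
            z_t = z_nom + rng.normal(0.0, noise.endpoint_sd_z)
            x_t = d + rng.normal(0.0, noise.endpoint_sd_x)
            if task.is_bar:
                lim = zh - 2e-3 * params.L
                z_t = float(np.clip(z_t, -lim, lim))
            # keep the jittered endpoint strictly reachable
            r = np.hypot(x_t, z_t)
            r_max = params.L * 0.999
            if r > r_max:
                x_t, z_t = x_t * r_max / r, z_t * r_max / r
            if noise.silent:
                traj = nominal.trajectory
                t_tr, q_tr = traj.t.copy(), traj.q.copy()
            elif resolve:
                sub = TaskSpec(q0=task.q0, T=task.T,
                               target=("point", (x_t, z_t)),
                               label=task.label)
                sol = solve_ocp(sub, true_weights, params, options, x0=warm)
                warm = sol.theta
                t_tr, q_tr = sol.trajectory.t.copy(), sol.trajectory.q.copy()
            else:
                traj = nominal.trajectory
                t_tr, q_tr = traj.t.copy(), traj.q.copy()
                # warp the joint path smoothly onto the jittered endpoint
                dq_end = inverse_kinematics(np.array([x_t, z_t]), params) \
                    - q_tr[-1]
                s = (t_tr - t_tr[0]) / (t_tr[-1] - t_tr[0])
                h = s**3 * (10 - 15 * s + 6 * s**2)
                q_tr = q_tr + h[:, None] * dq_end[None, :]
            if noise.kinematic_sd > 0:
                s = (t_tr - t_tr[0]) / (t_tr[-1] - t_tr[0])
                amp = noise.kinematic_sd / params.L  # radians giving ~sd m
                for k in (1, 2, 3):
                    a = rng.normal(0.0, amp / k, size=2)
                    q_tr = q_tr + np.sin(k * np.pi * s)[:, None] * a[None, :]
            if noise.duration_cv > 0:
                t_tr = t_tr * max(0.5, 1.0 + rng.normal(0.0, noise.duration_cv))
            # resample onto the 100 Hz recording grid
            t_rec = np.arange(0.0, t_tr[-1] + 1e-9, 1.0 / SAMPLING_HZ)
            q_rec = CubicSpline(t_tr, q_tr, axis=0)(np.clip(t_rec, 0, t_tr[-1]))
            trials.append(_trial_from_joint_path(t_rec, q_rec, params))
        reference = _average_reference(trials, params)
        postures[task.label or f"task{len(postures)}"] = PostureObservation(
            task=task, reference=reference, trials=trials)
    ground_truth = {
        "alpha": true_weights.alpha.tolist(),
        "s": true_weights.s.tolist(),
        "anchor": int(true_weights.anchor),
        "noise": asdict(noise),
        "n_trials": int(n_trials),
        "arm": params.to_dict(),
    }
    return ObservationSet(postures=postures, ground_truth=ground_truth)


def simulate_protocol(weight_sets: dict, subjects: Sequence[ArmParams],
                      tasks_per_subject: Optional[Sequence[Sequence[TaskSpec]]] = None,
                      options: Optional[SolverOptions] = None,
                      reference_paths: Optional[dict] = None) -> pd.DataFrame:
    """Cross every cost model with every subject and task.

    ``weight_sets`` maps model names to CostWeights; ``tasks_per_subject``
    gives one task list per subject (defaults to the standard five-posture
    protocol scaled to each subject's arm).  Returns a tidy table with one
    row per (model, subject, posture): solution costs, endpoint, and the
    kinematic features (RP, MV_angle, sIPC, coupling_R2, shape index);
    optionally the area to a per-posture reference path.  Per-cell solver
    failures are flagged in the ``status`` column and the run continues.
    """
    options = options or SolverOptions()
    rows = []
    for j, params in enumerate(subjects):
        tasks = (tasks_per_subject[j] if tasks_per_subject is not None
                 else default_tasks(params))
        for model, weights in weight_sets.items():
            for task in tasks:
                row = {"model": model, "subject": j, "posture": task.label}
                try:
                    sol = solve_ocp(task, weights, params, options)
                    summ = ka.summarize(sol.trajectory, task=task,
                                        params=params)
                    row.update(summ.to_dict())
                    row.update(total_cost=sol.total_cost, z_f=sol.z_f,
                               status=sol.status)
                    if reference_paths and task.label in reference_paths:
                        est = ka.area_between_paths(
                            sol.trajectory.pos,
                            reference_paths[task.label].pos,
                            seed=options.seed)
                        row["area_to_reference"] = est.area
                except Exception as exc:  # noqa: BLE001 - logged per cell
                    row.update(status=f"failed: {exc}")
                rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# observation-directory round trip (CSV + YAML + JSON, all plain text)


def _traj_frame(tr: Trajectory) -> pd.DataFrame:
    data = {"t": tr.t, "x": tr.pos[:, 0], "z": tr.pos[:, 1]}
    if tr.q is not None:
        data["q1"] = tr.q[:, 0]
        data["q2"] = tr.q[:, 1]
    return pd.DataFrame(data)


def _traj_from_frame(df: pd.DataFrame, params: ArmParams) -> Trajectory:
    t = df["t"].to_numpy()
    pos = df[["x", "z"]].to_numpy()
    if {"q1", "q2"}.issubset(df.columns):
        q = df[["q1", "q2"]].to_numpy()
    else:
        q = inverse_kinematics(pos, params)
    sp = CubicSpline(t, pos, axis=0)
    spq = CubicSpline(t, q, axis=0)
    return Trajectory(t=t, pos=pos, vel=sp(t, 1), acc=sp(t, 2), jerk=sp(t, 3),
                      q=q, qdot=spq(t, 1))


def save_observations(obs: ObservationSet, directory) -> None:
    root = Path(directory)
    root.mkdir(parents=True, exist_ok=True)
    (root / "ground_truth.json").write_text(
        json.dumps(obs.ground_truth, indent=1))
    for label, po in obs.postures.items():
        sub = root / label
        sub.mkdir(exist_ok=True)
        (sub / "task.yaml").write_text(yaml.safe_dump(po.task.to_dict()))
        _traj_frame(po.reference).to_csv(sub / "reference.csv", index=False)
        for i, tr in enumerate(po.trials):
            _traj_frame(tr).to_csv(sub / f"trial_{i:02d}.csv", index=False)


def load_observations(directory, params: Optional[ArmParams] = None) -> ObservationSet:
    root = Path(directory)
    gt_file = root / "ground_truth.json"
    ground_truth = json.loads(gt_file.read_text()) if gt_file.exists() else {}
    if params is None:
        params = (ArmParams.from_dict(ground_truth["arm"])
                  if "arm" in ground_truth else ArmParams())
    postures = {}
    for sub in sorted(p for p in root.iterdir() if p.is_dir()):
        task = TaskSpec.from_dict(yaml.safe_load((sub / "task.yaml").read_text()))
        reference = _traj_from_frame(pd.read_csv(sub / "reference.csv"), params)
        trials = [_traj_from_frame(pd.read_csv(f), params)
                  for f in sorted(sub.glob("trial_*.csv"))]
        postures[sub.name] = PostureObservation(task=task, reference=reference,
                                                trials=trials)
    return ObservationSet(postures=postures, ground_truth=ground_truth)
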