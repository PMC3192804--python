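"""Motion analysis: preprocessing and scalar movement features.

Mirrors the standard pipeline for point-to-bar reaching recordings:
zero-phase Butterworth low-pass filtering, 5%-of-peak-speed movement
windowing, 200-sample time normalization, and the descriptive features
used to compare models with data — duration, peak/mean speed and their
ratio (the speed-shape index, 1.875 for a minimum-jerk quintic), relative
time to peak speed, curvilinear distance, reached point, movement-vector
angle, the signed index of path curvature (sIPC), endpoint errors, the
endpoint consistency index (CI) and shoulder–elbow joint coupling.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Optional, Sequence

import numpy as np
from matplotlib.path import Path as _MplPath
from scipy.interpolate import CubicSpline
from scipy.signal import butter, filtfilt

from .arm_model import ArmParams, inverse_kinematics
from .cost_functions import Trajectory
from .direct_ocp import TaskSpec, reachable_half_length

__all__ = ["KinematicSummary", "preprocess", "summarize", "signed_path_curvature",
           "area_between_paths", "AreaEstimate"]

N_NORMALIZED = 200  # samples after time normalization
ONSET_FRACTION = 0.05  # speed threshold relative to its peak


@dataclass
class KinematicSummary:
    """Scalar movement features of one (averaged) trajectory.

    Trial-ensemble fields (variable_error, CI) are NaN unless trials are
    supplied; task-relative fields (RP, constant_error, CI) are NaN
    without a task/arm context.
    """

    MD: float  # movement duration (s)
    PV: float  # peak tangential speed (m/s)
    MV_vel: float  # mean tangential speed (m/s)
    TPV: float  # relative time to peak speed
    shape_index: float  # PV / MV_vel
    CD: float  # curvilinear distance (m)
    MV_angle: float  # movement-vector angle (deg, ccw from horizontal)
    sIPC: float  # signed index of path curvature
    RP: float = np.nan  # endpoint height / arm length
    constant_error: float = np.nan  # distance to the bar (m)
    variable_error: float = np.nan  # endpoint scatter across trials (m)
    CI: float = np.nan  # endpoint z SD / reachable-region length
    coupling_R2: float = np.nan  # shoulder-elbow determination coefficient

    def to_dict(self) -> dict:
        return asdict(self)


def _tangential_speed(t: np.ndarray, pos: np.ndarray) -> np.ndarray:
    vel = np.gradient(pos, t, axis=0)
    return np.linalg.norm(vel, axis=1)


def preprocess(t: np.ndarray, pos: np.ndarray, fs: Optional[float] = None,
               cutoff_hz: float = 10.0, order: int = 5,
               n_out: int = N_NORMALIZED,
               params: Optional[ArmParams] = None) -> Trajectory:
    """Filter, window and time-normalize a raw fingertip recording.

    A zero-phase (forward-backward) Butterworth low-pass of the given
    order and cutoff is applied to the position channels; the movement
    window runs from the first upward crossing of 5% of peak speed before
    the global speed peak to the last downward crossing after it; the
    window is resampled to ``n_out`` samples with cubic splines.  When arm
    parameters are given, joint angles are attached via inverse
    kinematics.

    Raises on flat signals (no movement) and on windows shorter than five
    samples.
    """
    t = np.asarray(t, dtype=float)
    pos = np.asarray(pos, dtype=float)
    if len(t) < 20:
        raise ValueError("need at least 20 samples to preprocess")
    if fs is None:
        fs = 1.0 / float(np.median(np.diff(t)))
    if fs <= 0:
        raise ValueError("sampling frequency must be positive")
    nyq = 0.5 * fs
    if cutoff_hz < nyq:
        b, a = butter(order, cutoff_hz / nyq)
        pos_f = filtfilt(b, a, pos, axis=0)
    else:  # already below the filter band; nothing to remove
        pos_f = pos
    speed = _tangential_speed(t, pos_f)
    peak = speed.max()
    if peak <= 0:
        raise ValueError("flat signal: zero peak speed, no movement to window")
    i_peak = int(np.argmax(speed))
    above = speed >= ONSET_FRACTION * peak
    # first crossing before the global peak, last crossing after it
    # (robust to multiple threshold crossings from tremor)
    i_on = i_peak
    while i_on > 0 and above[i_on - 1]:
        i_on -= 1
    i_off = i_peak
    while i_off < len(t) - 1 and above[i_off + 1]:
        i_off += 1
    if i_off - i_on + 1 < 5:
        raise ValueError("movement window shorter than 5 samples")
    t_w = t[i_on:i_off + 1]
    sp = CubicSpline(t_w, pos_f[i_on:i_off + 1], axis=0)
    t_new = np.linspace(t_w[0], t_w[-1], n_out)
    out = Trajectory(t=t_new, pos=sp(t_new), vel=sp(t_new, 1),
                     acc=sp(t_new, 2), jerk=sp(t_new, 3))
    if params is not None:
        out.q = inverse_kinematics(out.pos, params)
    return out


def signed_path_curvature(pos: np.ndarray) -> float:
    """Signed index of path curvature: maximum deviation of the path from
    the chord joining its endpoints, divided by the chord length, positive
    when the extreme point lies above the chord (concave path).

    Degenerate chords (start = end) raise ValueError.
    """
    pos = np.asarray(pos, dtype=float)
    p0, p1 = pos[0], pos[-1]
    chord = p1 - p0
    clen = np.linalg.norm(chord)
    if clen < 1e-12:
        raise ValueError("degenerate chord: start and end coincide, "
                         "sIPC undefined")
    u = chord / clen
    # normal oriented so that "above the chord" is positive
    n = np.array([-u[1], u[0]])
    if n[1] < 0 or (n[1] == 0 and n[0] < 0):
        n = -n
    dev = (pos - p0) @ n
    i = int(np.argmax(np.abs(dev)))
    return float(dev[i] / clen)


def _endpoint_stats(trials: Sequence[Trajectory]):
    ends = np.array([tr.pos[-1] for tr in trials])
    centroid = ends.mean(axis=0)
    variable = float(np.sqrt(np.mean(np.sum((ends - centroid) ** 2, axis=1))))
    sd_z = float(np.std(ends[:, 1], ddof=0))
    return variable, sd_z


def summarize(traj: Trajectory, task: Optional[TaskSpec] = None,
              params: Optional[ArmParams] = None,
              trials: Optional[Sequence[Trajectory]] = None) -> KinematicSummary:
    """Compute the full feature set of a (preprocessed) trajectory.

    ``trials`` enables the ensemble statistics (variable error, CI);
    ``task`` + ``params`` enable the task-relative ones (RP, constant
    error, CI normalization) and joint coupling via inverse kinematics
    when the trajectory carries no joint angles.
    """
    t = traj.t
    speed = traj.speed if traj.vel is not None else _tangential_speed(t, traj.pos)
    MD = traj.duration
    PV = float(speed.max())
    CD = float(np.trapezoid(speed, t))
    MV_vel = CD / MD
    i_peak = int(np.argmax(speed))
    TPV = float((t[i_peak] - t[0]) / MD)
    dp = traj.pos[-1] - traj.pos[0]
    MV_angle = float(np.degrees(np.arctan2(dp[1], dp[0])))
    sipc = signed_path_curvature(traj.pos)
    out = KinematicSummary(MD=MD, PV=PV, MV_vel=MV_vel, TPV=TPV,
                           shape_index=PV / MV_vel, CD=CD,
                           MV_angle=MV_angle, sIPC=sipc)
    q = traj.q
    if q is None and params is not None:
        q = inverse_kinematics(traj.pos, params)
    if q is not None:
        # determination coefficient of the elbow-on-shoulder linear fit
        q1, q2 = q[:, 0], q[:, 1]
        if np.ptp(q1) > 1e-12 and np.ptp(q2) > 1e-12:
            r = np.corrcoef(q1, q2)[0, 1]
            out.coupling_R2 = float(r**2)
        else:
            out.coupling_R2 = 1.0  # one joint frozen: trivially coupled
    if params is not None:
        out.RP = float(traj.pos[-1, 1] / params.L)
    if task is not None and task.is_bar:
        d = task.target[1]
        out.constant_error = float(abs(traj.pos[-1, 0] - d))
        if trials:
            var_err, sd_z = _endpoint_stats(trials)
            out.variable_error = var_err
            if params is not None:
                region = 2.0 * reachable_half_length(d, params)
                out.CI = sd_z / region
    elif trials:
        out.variable_error = _endpoint_stats(trials)[0]
    return out


@dataclass
class AreaEstimate:
    """Monte-Carlo area between two paths with its standard error."""

    area: float
    se: float
    n_samples: int


def area_between_paths(path_a: np.ndarray, path_b: np.ndarray,
                       n_samples: int = 100_000, seed: int = 0,
                       gap_tol: float = 0.01) -> AreaEstimate:
    """Monte-Carlo estimate of the area enclosed between two paths.

    The region is the polygon formed by path A followed by path B
    reversed; endpoint gaps below ``gap_tol`` metres are closed with
    straight segments, larger gaps raise.  Uniform samples in the joint
    bounding box are classified with even-odd point-in-polygon tests, so
    self-intersecting regions (paths that cross) count the geometric area
    between the curves.  Deterministic given the seed.
    """
    path_a = np.asarray(path_a, dtype=float)
    path_b = np.asarray(path_b, dtype=float)
    if n_samples < 1000:
        raise ValueError("need at least 1000 samples")
    for ea, eb in ((path_a[0], path_b[0]), (path_a[-1], path_b[-1])):
        if np.linalg.norm(ea - eb) > gap_tol:
            raise ValueError(
                f"path endpoints differ by {np.linalg.norm(ea - eb):.3f} m "
                f"(> {gap_tol} m); cannot close the region")
    if path_a.shape == path_b.shape and np.allclose(path_a, path_b):
        return AreaEstimate(area=0.0, se=0.0, n_samples=n_samples)
    poly = np.vstack([path_a, path_b[::-1]])
    lo = poly.min(axis=0)
    hi = poly.max(axis=0)
    box = float(np.prod(hi - lo))
    if box <= 0:
        return AreaEstimate(area=0.0, se=0.0, n_samples=n_samples)
    rng = np.random.default_rng(seed)
    pts = lo + rng.random((n_samples, 2)) * (hi - lo)
    inside = _MplPath(poly, closed=True).contains_points(pts)
    p_in = inside.mean()
    area = box * p_in
    se = box * np.sqrt(p_in * (1.0 - p_in) / n_samples)
    return AreaEstimate(area=float(area), se=float(se), n_samples=n_samples)
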