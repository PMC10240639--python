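"""Inverse kinematics, stance detection, approach velocity, normalization.

Inverse kinematics solves, frame by frame, the weighted least-squares pose

    min_q  sum_m  w_m * || x_model_m(q) - x_measured_m ||^2

over the five planar degrees of freedom (pelvis translation + hip, knee,
ankle angles) using damped Gauss-Newton (Levenberg-Marquardt) with the
previous frame's solution as the warm start.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares
from scipy.signal import butter, filtfilt

from .errors import GapError, InputError, InsufficientHistoryError, NoStanceError

_MAX_GAP_FRAMES = 10


@dataclass
class MarkerTimeSeries:
    """Planar marker trajectories: name -> (n, 2) array of (x, y) in metres."""

    time: np.ndarray
    markers: dict[str, np.ndarray]
    units: str = "m"
    rate: float | None = None

    def __post_init__(self):
        self.time = np.asarray(self.time, dtype=float)
        n = self.time.size
        for name, arr in self.markers.items():
            arr = np.asarray(arr, dtype=float)
            if arr.shape != (n, 2):
                raise InputError(f"marker {name!r}: expected shape ({n}, 2), got {arr.shape}")
            self.markers[name] = arr
        if self.rate is None and n > 1:
            self.rate = 1.0 / float(np.mean(np.diff(self.time)))

    @property
    def names(self) -> list[str]:
        return list(self.markers)


@dataclass
class JointKinematics:
    """Joint angles (deg) and derivatives plus the pelvis trajectory."""

    time: np.ndarray
    angles: dict[str, np.ndarray]               # deg; knee flexion positive
    angular_velocity: dict[str, np.ndarray]     # deg/s
    angular_acceleration: dict[str, np.ndarray]  # deg/s^2
    pelvis: np.ndarray                          # (n, 2) hip-joint position, m
    objective: np.ndarray | None = None         # per-frame weighted SSE
    interpolated: np.ndarray | None = None      # frames filled across gaps
    meta: dict = field(default_factory=dict)

    @classmethod
    def from_pose_trajectory(cls, time, q, **meta) -> "JointKinematics":
        """Build from a (n, 5) pose trajectory, differentiating numerically
        (central differences; one-sided at the ends)."""
        time = np.asarray(time, dtype=float)
        q = np.asarray(q, dtype=float)
        angles = {j: q[:, 2 + i].copy() for i, j in enumerate(("hip", "knee", "ankle"))}
        if time.size > 1:
            vel = {j: np.gradient(a, time) for j, a in angles.items()}
            acc = {j: np.gradient(v, time) for j, v in vel.items()}
        else:
            vel = {j: np.zeros_like(a) for j, a in angles.items()}
            acc = {j: np.zeros_like(a) for j, a in angles.items()}
        return cls(time=time, angles=angles, angular_velocity=vel,
                   angular_acceleration=acc, pelvis=q[:, :2].copy(), meta=dict(meta))

    def pose_trajectory(self) -> np.ndarray:
        """(n, 5) array in the model's q layout."""
        return np.column_stack([self.pelvis,
                                self.angles["hip"], self.angles["knee"], self.angles["ankle"]])


# ---------------------------------------------------------------------------
# inverse kinematics


def _frame_residual_jac(model, names, weights, obs, q):
    """Weighted residual vector and analytic Jacobian for one frame.

    q = (px, py, hip_rad, knee_rad, ankle_rad).
    """
    qdeg = np.array([q[0], q[1], np.degrees(q[2]), np.degrees(q[3]), np.degrees(q[4])])
    pose = model.pose(qdeg)
    joints = {k: v[0] for k, v in pose["joints"].items()}
    positions = model.marker_positions(qdeg, names)
    distal = {"pelvis": (), "thigh": ("hip",), "shank": ("hip", "knee"),
              "foot": ("hip", "knee", "ankle")}
    sign = {"hip": 1.0, "knee": -1.0, "ankle": 1.0}
    col = {"hip": 2, "knee": 3, "ankle": 4}

    res = np.empty(2 * len(names))
    jac = np.zeros((2 * len(names), 5))
    for i, name in enumerate(names):
        seg = model.marker_map[name][0]
        p = positions[name][0]
        sw = np.sqrt(weights[i])
        res[2 * i:2 * i + 2] = sw * (p - obs[i])
        jac[2 * i, 0] = sw
        jac[2 * i + 1, 1] = sw
        for joint in distal[seg]:
            r = p - joints[joint]
            jac[2 * i, col[joint]] = sw * sign[joint] * (-r[1])
            jac[2 * i + 1, col[joint]] = sw * sign[joint] * r[0]
    return res, jac


def inverse_kinematics(markers: MarkerTimeSeries, model, *,
                       initial_guess=None, free_pelvis: bool = True,
                       fixed_pelvis=None, max_gap: int = _MAX_GAP_FRAMES) -> JointKinematics:
    """Per-frame weighted least-squares pose fit.

    Markers with any NaN coordinate in a frame are treated as missing for
    that frame.  Frames with fewer than three visible markers are flagged
    and linearly interpolated when the gap is at most ``max_gap`` frames;
    longer gaps reject the trial with :class:`GapError`.

    ``free_pelvis=False`` fixes the pelvis translation at ``fixed_pelvis``
    (useful for oracle comparisons over the three joint angles only).
    """
    names_all = [n for n in markers.names if n in model.marker_map
                 and model.marker_weights.get(n, 1.0) > 0]
    if len(names_all) < 3:
        raise InputError("need at least 3 positively weighted markers")
    n = markers.time.size
    q = np.zeros((n, 5))
    obj = np.zeros(n)
    bad = np.zeros(n, dtype=bool)

    if initial_guess is None:
        guess = np.array([0.0, model.standing_pelvis_height(20.0, 20.0),
                          np.radians(20.0), np.radians(20.0), 0.0])
        sacr = next((m for m in names_all if model.marker_map[m][0] == "pelvis"), None)
        if sacr is not None and np.isfinite(markers.markers[sacr][0]).all():
            seg, off = model.marker_map[sacr]
            loff = np.array(off) * model.segments[seg].length
            guess[:2] = markers.markers[sacr][0] - loff
    else:
        guess = np.array([initial_guess[0], initial_guess[1],
                          *np.radians(initial_guess[2:])], dtype=float)

    for i in range(n):
        vis = [m for m in names_all if np.isfinite(markers.markers[m][i]).all()]
        if len(vis) < 3:
            bad[i] = True
            continue
        w = np.array([model.marker_weights.get(m, 1.0) for m in vis])
        obs = np.stack([markers.markers[m][i] for m in vis])

        if free_pelvis:
            def fun(x):
                return _frame_residual_jac(model, vis, w, obs, x)[0]

            def jac(x):
                return _frame_residual_jac(model, vis, w, obs, x)[1]

            sol = least_squares(fun, guess, jac=jac, method="lm",
                                xtol=1e-15, ftol=1e-15, gtol=1e-15, max_nfev=400)
            q[i] = sol.x
            obj[i] = np.sum(sol.fun**2)
            guess = sol.x.copy()
        else:
            pelvis = np.asarray(fixed_pelvis, dtype=float)
            pelvis = pelvis[i] if pelvis.ndim == 2 else pelvis

            def fun(x):
                return _frame_residual_jac(model, vis, w, obs,
                                           np.concatenate([pelvis, x]))[0]

            def jac(x):
                return _frame_residual_jac(model, vis, w, obs,
                                           np.concatenate([pelvis, x]))[1][:, 2:]

            sol = least_squares(fun, guess[2:], jac=jac, method="lm",
                                xtol=1e-15, ftol=1e-15, gtol=1e-15, max_nfev=400)
            q[i] = np.concatenate([pelvis, sol.x])
            obj[i] = np.sum(sol.fun**2)
            guess = np.concatenate([pelvis, sol.x])

    if bad.any():
        _interpolate_gaps(markers.time, q, bad, max_gap)

    qdeg = q.copy()
    qdeg[:, 2:] = np.degrees(q[:, 2:])
    kin = JointKinematics.from_pose_trajectory(markers.time, qdeg)
    kin.objective = obj
    kin.interpolated = bad
    return kin


def _interpolate_gaps(time, q, bad, max_gap):
    idx = np.flatnonzero(bad)
    runs = np.split(idx, np.flatnonzero(np.diff(idx) > 1) + 1)
    for run in runs:
        if run.size > max_gap:
            raise GapError(f"marker gap of {run.size} frames exceeds {max_gap}")
        lo, hi = run[0] - 1, run[-1] + 1
        if lo < 0 or hi >= len(time):
            raise GapError("marker gap at the record boundary cannot be interpolated")
        for col in range(q.shape[1]):
            q[run, col] = np.interp(time[run], [time[lo], time[hi]], [q[lo, col], q[hi, col]])


# ---------------------------------------------------------------------------
# events, velocity, normalization, filtering


def detect_stance(vertical_force, threshold: float = 20.0) -> tuple[int, int]:
    """First and last sample index (inclusive) with raw force above threshold.

    Operates on the unfiltered vertical force at its native rate.
    """
    if threshold <= 0:
        raise InputError("stance threshold must be > 0")
    f = np.asarray(vertical_force, dtype=float)
    above = np.flatnonzero(f > threshold)
    if above.size == 0:
        raise NoStanceError(f"no sample exceeds {threshold} N")
    return int(above[0]), int(above[-1])


def approach_velocity(time, com_x, contact_time: float, window: float = 0.050) -> float:
    """Mean forward COM velocity over the ``window`` seconds before contact.

    Computed as the position difference across the window divided by its
    duration, with positions linearly interpolated at the endpoints (this is
    exactly the time average of the sampled velocity profile).
    """
    if window <= 0:
        raise InputError("window must be > 0")
    time = np.asarray(time, dtype=float)
    com_x = np.asarray(com_x, dtype=float)
    t0 = contact_time - window
    if t0 < time[0] - 1e-12 or contact_time > time[-1] + 1e-12:
        raise InsufficientHistoryError(
            f"trajectory [{time[0]:.4f}, {time[-1]:.4f}] s does not cover "
            f"[{t0:.4f}, {contact_time:.4f}] s")
    x0 = float(np.interp(t0, time, com_x))
    x1 = float(np.interp(contact_time, time, com_x))
    return (x1 - x0) / window


def com_trajectory(kin: JointKinematics, model) -> np.ndarray:
    """Mass-weighted whole-chain COM trajectory from full kinematics."""
    return model.com(kin.pose_trajectory())


def sacral_proxy_com(markers: MarkerTimeSeries, name: str = "SACR") -> np.ndarray:
    """Sacral-marker COM proxy for when full kinematics are unavailable."""
    if name not in markers.markers:
        raise InputError(f"marker {name!r} not present")
    return markers.markers[name]


def time_normalize(time, values, interval) -> np.ndarray:
    """Linearly resample onto 0-100% of ``interval`` (101 samples)."""
    time = np.asarray(time, dtype=float)
    values = np.asarray(values, dtype=float)
    t0, t1 = interval
    if not t1 > t0:
        raise InputError("interval end must exceed start")
    if t0 < time[0] - 1e-12 or t1 > time[-1] + 1e-12:
        raise InputError("interval outside the record")
    query = np.linspace(t0, t1, 101)
    return np.interp(query, time, values)


def lowpass(values, rate: float, cutoff: float, order: int = 4) -> np.ndarray:
    """Zero-lag Butterworth low-pass along axis 0 (``filtfilt``)."""
    values = np.asarray(values, dtype=float)
    if cutoff <= 0 or cutoff >= rate / 2:
        raise InputError("cutoff must lie in (0, Nyquist)")
    b, a = butter(order, cutoff / (rate / 2.0))
    padlen = min(3 * (max(len(a), len(b)) - 1), values.shape[0] - 1)
    return filtfilt(b, a, values, axis=0, padlen=padlen)


def filter_markers(markers: MarkerTimeSeries, cutoff: float = 12.0) -> MarkerTimeSeries:
    """Low-pass every marker trajectory (default 4th-order zero-lag, 12 Hz)."""
    rate = markers.rate or 1.0 / float(np.mean(np.diff(markers.time)))
    return MarkerTimeSeries(
        time=markers.time.copy(),
        markers={k: lowpass(v, rate, cutoff) for k, v in markers.markers.items()},
        units=markers.units, rate=rate)
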