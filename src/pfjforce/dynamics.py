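"""Bottom-up Newton-Euler inverse dynamics on the planar chain.

Net joint moments are computed foot -> shank -> thigh from segment inertial
terms (m*a, I*alpha), gravity and the measured ground reaction, and reported
about the joint centres with the package sign conventions (hip flexion,
knee extension and ankle plantarflexion positive).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import AlignmentError, InputError

_COP_FORCE_EPS = 1.0  # N; below this the ground reaction is treated as absent


@dataclass
class GRFSeries:
    """Ground reaction: planar force, centre of pressure and free moment.

    The force is applied at ``(cop_x, ground_y)``; ``free_mz`` is an
    additional moment about that point (zero for measured data, used
    internally when inverting the dynamics).
    """

    time: np.ndarray
    fx: np.ndarray
    fy: np.ndarray
    cop_x: np.ndarray
    free_mz: np.ndarray | None = None
    ground_y: float = 0.0
    rate: float | None = None

    def __post_init__(self):
        self.time = np.asarray(self.time, dtype=float)
        n = self.time.size
        for name in ("fx", "fy", "cop_x"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != (n,):
                raise InputError(f"grf field {name!r}: expected shape ({n},)")
            setattr(self, name, arr)
        if self.free_mz is None:
            self.free_mz = np.zeros(n)
        else:
            self.free_mz = np.asarray(self.free_mz, dtype=float)
        if self.rate is None and n > 1:
            self.rate = 1.0 / float(np.mean(np.diff(self.time)))

    @property
    def magnitude(self) -> np.ndarray:
        return np.hypot(self.fx, self.fy)

    @classmethod
    def zeros_like(cls, time, ground_y: float = 0.0) -> "GRFSeries":
        n = np.asarray(time).size
        return cls(time=np.asarray(time, dtype=float), fx=np.zeros(n), fy=np.zeros(n),
                   cop_x=np.zeros(n), ground_y=ground_y)


@dataclass
class NetJointMoments:
    """Net joint moments (N m) per joint per sample."""

    time: np.ndarray
    moments: dict[str, np.ndarray]   # hip flexion +, knee extension +, ankle PF +
    grf: GRFSeries | None = None
    meta: dict = field(default_factory=dict)

    def stacked(self) -> np.ndarray:
        """(n, 3) array in (hip, knee, ankle) order."""
        return np.column_stack([self.moments[j] for j in ("hip", "knee", "ankle")])


def _cross(r, f):
    """z-component of the planar cross product r x f for (n, 2) arrays."""
    return r[:, 0] * f[:, 1] - r[:, 1] * f[:, 0]


def _segment_states(kin, model):
    """Per-segment COM kinematics and angular accelerations."""
    q = kin.pose_trajectory()
    pose = model.pose(q)
    coms = model.segment_coms(q)
    t = kin.time
    out = {}
    for name in ("thigh", "shank", "foot"):
        c = coms[name]
        vel = np.gradient(c, t, axis=0)
        acc = np.gradient(vel, t, axis=0)
        phi = pose["phi"][name]
        alpha = np.gradient(np.gradient(phi, t), t)
        out[name] = {"com": c, "acc": acc, "alpha": alpha}
    return out, pose["joints"]


def inverse_dynamics(kin, grf: GRFSeries, model) -> NetJointMoments:
    """Net hip/knee/ankle moments from kinematics and the ground reaction.

    ``kin`` and ``grf`` must share a time base.  The centre of pressure must
    be finite wherever the force magnitude exceeds 1 N.
    """
    t = np.asarray(kin.time, dtype=float)
    if grf.time.shape != t.shape or np.max(np.abs(grf.time - t)) > 1e-9:
        raise AlignmentError("kinematics and GRF time bases are not aligned")
    loaded = np.hypot(grf.fx, grf.fy) > _COP_FORCE_EPS
    if np.any(loaded & ~np.isfinite(grf.cop_x)):
        raise InputError("centre of pressure missing while the foot is loaded")

    states, joints = _segment_states(kin, model)
    g = np.array([0.0, -model.gravity])
    n = t.size

    fgrf = np.column_stack([grf.fx, grf.fy])
    cop = np.column_stack([np.where(np.isfinite(grf.cop_x), grf.cop_x, 0.0),
                           np.full(n, grf.ground_y)])

    def step(seg_name, prox_joint, f_dist, m_dist, p_dist):
        seg = model.segments[seg_name]
        st = states[seg_name]
        p_prox = joints[prox_joint]
        f_prox = seg.mass * (st["acc"] - g) - f_dist
        m_prox = (seg.inertia * st["alpha"]
                  - m_dist
                  - _cross(p_dist - st["com"], f_dist)
                  - _cross(p_prox - st["com"], f_prox))
        return f_prox, m_prox

    f_ankle, m_ankle = step("foot", "ankle", fgrf, grf.free_mz, cop)
    f_knee, m_knee = step("shank", "knee", -f_ankle, -m_ankle, joints["ankle"])
    f_hip, m_hip = step("thigh", "hip", -f_knee, -m_knee, joints["knee"])

    moments = {
        "hip": m_hip,          # CCW on thigh = flexion
        "knee": m_knee,        # CCW on shank = extension
        "ankle": -m_ankle,     # CW on foot = plantarflexion
    }
    return NetJointMoments(time=t, moments=moments, grf=grf,
                           meta={"sign_convention": "hip flex+/knee ext+/ankle pf+"})


def grf_for_target_moments(kin, targets: np.ndarray, model,
                           active: np.ndarray | None = None) -> GRFSeries:
    """Invert the dynamics: the ground reaction producing given net moments.

    ``targets`` is (n, 3) in (hip, knee, ankle) order with package sign
    conventions.  Per frame the planar wrench (fx, fy, free moment at the
    ground origin) is solved from a 3x3 linear system built by unit-load
    evaluation of :func:`inverse_dynamics`, then re-expressed as a force at
    a centre of pressure.  ``active`` masks frames where a reaction should
    be applied (elsewhere the output is zero).
    """
    t = np.asarray(kin.time, dtype=float)
    n = t.size
    targets = np.asarray(targets, dtype=float)
    if targets.shape != (n, 3):
        raise InputError(f"targets must have shape ({n}, 3)")
    active = np.ones(n, dtype=bool) if active is None else np.asarray(active, dtype=bool)

    base = inverse_dynamics(kin, GRFSeries.zeros_like(t), model).stacked()
    cols = []
    for fx, fy, mz in ((1.0, 0.0, 0.0), (0.0, 1.0, 0.0), (0.0, 0.0, 1.0)):
        unit = GRFSeries(time=t, fx=np.full(n, fx), fy=np.full(n, fy),
                         cop_x=np.zeros(n), free_mz=np.full(n, mz))
        cols.append(inverse_dynamics(kin, unit, model).stacked() - base)
    mats = np.stack(cols, axis=2)          # (n, 3 joints, 3 unknowns)
    rhs = targets - base
    wrench = np.zeros((n, 3))
    wrench[active] = np.linalg.solve(mats[active], rhs[active][..., None])[..., 0]

    fx, fy, mz = wrench[:, 0], wrench[:, 1], wrench[:, 2]
    # fold the free moment into the centre of pressure where possible
    with np.errstate(divide="ignore", invalid="ignore"):
        cop = np.where(np.abs(fy) > _COP_FORCE_EPS, mz / fy, 0.0)
    residual_mz = np.where(np.abs(fy) > _COP_FORCE_EPS, 0.0, mz)
    return GRFSeries(time=t, fx=fx, fy=fy, cop_x=cop, free_mz=residual_mz,
                     ground_y=0.0)
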