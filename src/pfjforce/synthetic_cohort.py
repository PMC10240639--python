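"""Synthetic cutting-trial cohorts at two fidelity levels.

Metric level: trial-rows of scalar outcomes with participant random
intercepts, within-trial correlated noise, and a velocity covariate, so the
downstream mixed model's assumed structure holds by construction.

Signal level: full marker/ground-reaction time series for one stance-phase
trial.  Joint-angle and demand waveforms are raised-cosine shapes peaking
mid-stance; the ground reaction is obtained by inverting the planar
dynamics for the designed net-moment curves, which makes the noiseless
trial exactly consistent with the IK -> ID -> SO -> PFJ pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml
from scipy.optimize import brentq

from . import kinematics as kn
from . import metrics_stats as ms
from .dynamics import GRFSeries, grf_for_target_moments, inverse_dynamics
from .errors import ConfigurationError
from .muscle_forces import static_optimization, quadriceps_force
from .pfj_model import PatellarMechanism, pfj_series
from .resources import default_path

METRICS = ("peak_pfj_bw", "knee_angle_deg", "quad_force_bw")


# ---------------------------------------------------------------------------
# design


@dataclass
class LimbCalibration:
    mu: dict[str, float]
    sd_between: dict[str, float]
    sd_within: dict[str, float]
    velocity_mean: float
    velocity_sd: float


@dataclass
class CohortDesign:
    """Cohort structure and outcome calibration for the generator."""

    n_aclr: int
    n_control: int
    trials_per_limb: int
    limbs: dict[str, LimbCalibration]
    velocity_slope: dict[str, float]
    metric_correlation: np.ndarray
    signal: dict = field(default_factory=dict)
    seed: int = 0
    version: int = 0

    def __post_init__(self):
        self.metric_correlation = np.asarray(self.metric_correlation, dtype=float)
        self.validate()

    def validate(self) -> None:
        if self.n_aclr < 2:
            raise ConfigurationError("n_aclr must be >= 2")
        if self.n_control < 2:
            raise ConfigurationError("n_control must be >= 2")
        if self.trials_per_limb < 1:
            raise ConfigurationError("trials_per_limb must be >= 1")
        for limb in ("ACLR", "contralateral", "control"):
            if limb not in self.limbs:
                raise ConfigurationError(f"limbs: missing calibration for {limb!r}")
        for limb, cal in self.limbs.items():
            for m in METRICS:
                if cal.sd_between.get(m, 0.0) < 0:
                    raise ConfigurationError(f"limbs[{limb}].sd_between[{m}] must be >= 0")
                if cal.sd_within.get(m, 0.0) < 0:
                    raise ConfigurationError(f"limbs[{limb}].sd_within[{m}] must be >= 0")
            if cal.velocity_sd < 0:
                raise ConfigurationError(f"limbs[{limb}].velocity.sd must be >= 0")
        corr = self.metric_correlation
        if corr.shape != (3, 3) or not np.allclose(corr, corr.T):
            raise ConfigurationError("metric_correlation must be a symmetric 3x3 matrix")
        if np.max(np.abs(corr)) > 1.0 + 1e-12:
            raise ConfigurationError("metric_correlation entries must lie in [-1, 1]")
        if np.min(np.linalg.eigvalsh(corr)) < -1e-10:
            raise ConfigurationError("metric_correlation must be positive semidefinite")

    @classmethod
    def from_yaml(cls, path=None, **overrides) -> "CohortDesign":
        """Load the versioned defaults file (or another design file)."""
        path = default_path("cohort_defaults.yaml") if path is None else path
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        limbs = {
            name: LimbCalibration(
                mu={k: float(v) for k, v in spec["mu"].items()},
                sd_between={k: float(v) for k, v in spec["sd_between"].items()},
                sd_within={k: float(v) for k, v in spec["sd_within"].items()},
                velocity_mean=float(spec["velocity"]["mean"]),
                velocity_sd=float(spec["velocity"]["sd"]),
            )
            for name, spec in raw["limbs"].items()
        }
        kwargs = dict(
            n_aclr=int(raw["n_aclr"]),
            n_control=int(raw["n_control"]),
            trials_per_limb=int(raw["trials_per_limb"]),
            limbs=limbs,
            velocity_slope={k: float(v) for k, v in raw["velocity_slope"].items()},
            metric_correlation=np.asarray(raw["metric_correlation"], dtype=float),
            signal=dict(raw.get("signal", {})),
            version=int(raw.get("version", 0)),
        )
        kwargs.update(overrides)
        return cls(**kwargs)

    def pooled_velocity_mean(self) -> float:
        """Expected velocity pooled over all rows of the design."""
        weights = {"ACLR": self.n_aclr, "contralateral": self.n_aclr,
                   "control": self.n_control}
        total = sum(weights.values())
        return sum(weights[l] * self.limbs[l].velocity_mean for l in weights) / total


# ---------------------------------------------------------------------------
# metric-level generator


def generate_metric_cohort(design: CohortDesign, seed: int) -> pd.DataFrame:
    """Trial-level table of scalar outcomes with the model's assumed structure.

    For metric m on limb L of participant p, trial t:

        y = mu_m(L) + b_pm + slope_m * (v_pt - v_pooled) + eps_mt

    with b ~ N(0, sd_between), eps ~ N(0, sd_within) (correlated across the
    three metrics), v ~ N per-limb; ACLR and contralateral rows of the same
    participant share b.  Deterministic for a fixed seed.
    """
    design.validate()
    rng = np.random.default_rng(seed)
    chol = np.linalg.cholesky(
        design.metric_correlation + 1e-12 * np.eye(3))
    v_pooled = design.pooled_velocity_mean()
    rows = []

    def trial_rows(pid, limb, b):
        cal = design.limbs[limb]
        for trial in range(1, design.trials_per_limb + 1):
            v = rng.normal(cal.velocity_mean, cal.velocity_sd)
            eps = chol @ rng.standard_normal(3)
            row = {"participant_id": pid, "limb": limb, "trial": trial,
                   "approach_velocity_ms": v}
            for i, m in enumerate(METRICS):
                row[m] = (cal.mu[m] + b[i]
                          + design.velocity_slope.get(m, 0.0) * (v - v_pooled)
                          + cal.sd_within.get(m, 0.0) * eps[i])
            rows.append(row)

    for p in range(1, design.n_aclr + 1):
        pid = f"A{p:03d}"
        cal = design.limbs["ACLR"]
        z = chol @ rng.standard_normal(3)
        b = np.array([cal.sd_between.get(m, 0.0) for m in METRICS]) * z
        for limb in ("ACLR", "contralateral"):
            trial_rows(pid, limb, b)
    for p in range(1, design.n_control + 1):
        pid = f"C{p:03d}"
        cal = design.limbs["control"]
        z = chol @ rng.standard_normal(3)
        b = np.array([cal.sd_between.get(m, 0.0) for m in METRICS]) * z
        trial_rows(pid, "control", b)

    return pd.DataFrame(rows, columns=list(ms.METRIC_COLUMNS))


# ---------------------------------------------------------------------------
# signal-level generator


@dataclass
class NoiseSpec:
    marker_sd: float = 0.0   # m, isotropic per coordinate
    grf_sd: float = 0.0      # N, per force component

    def __post_init__(self):
        if self.marker_sd < 0 or self.grf_sd < 0:
            raise ConfigurationError("noise SDs must be >= 0")


@dataclass
class TrialTimeSeries:
    """Observed (possibly noisy) signals for one trial."""

    markers: kn.MarkerTimeSeries
    grf: GRFSeries
    body_mass: float
    height: float
    meta: dict = field(default_factory=dict)


@dataclass
class TrialGroundTruth:
    """Noise-free internals of a generated trial."""

    kinematics: kn.JointKinematics
    net_moments: object            # NetJointMoments on the marker clock
    muscle_solution: object        # MuscleSolution over stance frames
    quad_force_bw: np.ndarray      # over stance frames
    pfj: object                    # PFJForceSeries over stance frames
    stance_frames: np.ndarray      # marker-frame indices within stance
    contact_time: float
    approach_velocity: float
    metrics: ms.StanceMetrics


def forward_markers(kin_or_q, model, time=None) -> kn.MarkerTimeSeries:
    """Marker trajectories from planar forward kinematics.

    Accepts a :class:`JointKinematics` or a ``(n, 5)`` pose trajectory.
    Exact inverse of noiseless IK up to solver tolerance.
    """
    if hasattr(kin_or_q, "pose_trajectory"):
        q = kin_or_q.pose_trajectory()
        time = kin_or_q.time
    else:
        q = np.atleast_2d(np.asarray(kin_or_q, dtype=float))
        if time is None:
            time = np.arange(q.shape[0], dtype=float)
    return kn.MarkerTimeSeries(time=np.asarray(time, dtype=float),
                               markers=model.marker_positions(q))


def _window(t, t0, t_peak, t1):
    """C1 raised-cosine bump: 0 at t0/t1, 1 at t_peak, flat at all three."""
    t = np.asarray(t, dtype=float)
    w = np.zeros_like(t)
    up = (t >= t0) & (t <= t_peak)
    dn = (t > t_peak) & (t <= t1)
    w[up] = 0.5 - 0.5 * np.cos(np.pi * (t[up] - t0) / (t_peak - t0))
    w[dn] = 0.5 + 0.5 * np.cos(np.pi * (t[dn] - t_peak) / (t1 - t_peak))
    return w


def generate_signal_trial(design: CohortDesign, limb: str, noise: NoiseSpec,
                          seed: int, model=None, *, velocity: float | None = None,
                          angle_peak: float | None = None,
                          quad_peak_bw: float | None = None
                          ) -> tuple[TrialTimeSeries, TrialGroundTruth]:
    """One stance-phase cutting trial with self-consistent ground truth.

    The knee flexion curve rises to ``angle_peak`` mid-stance and the net
    joint moment demand is scaled (by root-finding on the static
    optimization) so that the ground-truth quadriceps force peaks at
    ``quad_peak_bw``.  The ground reaction realizing those moments is then
    solved from the inverse dynamics, so a noiseless pipeline run reproduces
    the ground truth to solver tolerance.  Noise perturbs observations only;
    two seeds with identical calibration inputs share their ground truth.
    """
    from .model import PlanarModel

    if model is None:
        model = PlanarModel.from_yaml()
    sig = design.signal
    if float(sig.get("stance_duration_s", 0.25)) <= 0:
        raise ConfigurationError("stance duration must be > 0")
    cal = design.limbs[limb]
    seq = np.random.SeedSequence([int(seed), 0x5f3])
    rng_truth, rng_noise = (np.random.default_rng(s) for s in seq.spawn(2))

    if velocity is None:
        velocity = float(rng_truth.normal(cal.velocity_mean, cal.velocity_sd))
    if angle_peak is None:
        angle_peak = (cal.mu["knee_angle_deg"]
                      + design.velocity_slope.get("knee_angle_deg", 0.0)
                      * (velocity - cal.velocity_mean))
    if quad_peak_bw is None:
        quad_peak_bw = (cal.mu["quad_force_bw"]
                        + design.velocity_slope.get("quad_force_bw", 0.0)
                        * (velocity - cal.velocity_mean))

    t_st = float(sig.get("stance_duration_s", 0.25))
    t_pre = float(sig.get("precontact_duration_s", 0.12))
    fs_m = float(sig.get("marker_rate_hz", 250.0))
    fs_g = float(sig.get("grf_rate_hz", 1000.0))
    frac = float(sig.get("peak_fraction_of_stance", 0.45))
    knee0 = float(sig.get("knee_angle_at_contact_deg", 22.0))
    hip0 = float(sig.get("hip_angle_at_contact_deg", 30.0))
    hip1 = float(sig.get("hip_angle_peak_deg", 50.0))
    vloss = float(sig.get("velocity_loss_fraction", 0.35))
    ratios = np.array([float(sig.get("hip_demand_ratio", -0.4)), 1.0,
                       float(sig.get("ankle_demand_ratio", 0.5))])

    # --- true pose trajectory on the marker clock (t = 0 at nominal contact)
    n_pre = int(round(t_pre * fs_m))
    n_st = int(round(t_st * fs_m))
    tm = (np.arange(-n_pre, n_st + 1)) / fs_m
    t_peak = frac * t_st
    w = _window(tm, 0.0, t_peak, t_st)
    knee = knee0 + (angle_peak - knee0) * w
    hip = hip0 + (hip1 - hip0) * w
    ankle = np.zeros_like(tm)

    # forward speed: constant before contact, raised-cosine deceleration after
    decel = np.where((tm > 0) & (tm < t_st),
                     (2.0 * vloss * velocity / t_st) * np.sin(np.pi * np.clip(tm, 0, t_st) / t_st) ** 2,
                     0.0)
    vx = velocity - np.concatenate([[0.0], np.cumsum((decel[1:] + decel[:-1]) / 2.0) / fs_m])
    px = np.concatenate([[0.0], np.cumsum((vx[1:] + vx[:-1]) / 2.0) / fs_m])
    px -= np.interp(0.0, tm, px)
    # pelvis height keeps the planted ankle at its nominal height
    lt = model.segments["thigh"].length
    lsh = model.segments["shank"].length
    py = (model.ankle_height + lt * np.cos(np.radians(hip))
          + lsh * np.cos(np.radians(hip - knee)))
    q = np.column_stack([px, py, hip, knee, ankle])
    kin_true = kn.JointKinematics.from_pose_trajectory(tm, q)

    # --- net-moment targets: demand bump scaled to hit the quad-force peak
    base = inverse_dynamics(kin_true, GRFSeries.zeros_like(tm), model).stacked()
    i_peak = int(np.argmin(np.abs(tm - t_peak)))
    stance_mask = (tm >= 0.0) & (tm <= t_st)

    def quad_at_peak(c):
        m = base[i_peak] + c * ratios
        sol = _so_single(m, kin_true, model, i_peak)
        return quadriceps_force(sol, model.body_mass, model.gravity)[0] - quad_peak_bw

    c_star = brentq(quad_at_peak, 1.0, 3000.0, xtol=1e-9)
    targets = base + np.outer(w, c_star * ratios)

    grf_true = grf_for_target_moments(kin_true, targets, model, active=stance_mask)
    moments_true = _moments_from(targets, tm, grf_true)

    # --- ground-truth muscle forces / PFJ over stance frames
    stance_frames = np.flatnonzero(stance_mask)
    kin_st = _slice_kin(kin_true, stance_frames)
    sol = static_optimization(_moments_from(targets[stance_frames], tm[stance_frames], None),
                              kin_st, model)
    quad_bw = quadriceps_force(sol, model.body_mass, model.gravity)
    pfj_true = pfj_series(quad_bw, kin_st, model.mechanism)

    # --- native-rate GRF record
    tg = np.arange(int(round((tm[-1] + t_pre) * fs_g)) + 1) / fs_g - t_pre
    fx_g = np.interp(tg, tm, grf_true.fx)
    fy_g = np.interp(tg, tm, grf_true.fy)
    cop_g = np.interp(tg, tm, grf_true.cop_x)
    outside = (tg < 0) | (tg > t_st)
    fx_g[outside] = 0.0
    fy_g[outside] = 0.0

    i0, i1 = kn.detect_stance(fy_g, 20.0)
    contact_time = float(tg[i0])
    v_true = kn.approach_velocity(tm, model.com(q)[:, 0], contact_time)

    metrics_true = ms.extract_metrics(
        pfj_true, kin_st, np.arange(stance_frames.size), v_true,
        participant_id="truth", limb=limb if limb in ms.LIMB_LEVELS else "ACLR",
        trial=0, exclude=sol.infeasible)

    truth = TrialGroundTruth(
        kinematics=kin_true, net_moments=moments_true, muscle_solution=sol,
        quad_force_bw=quad_bw, pfj=pfj_true, stance_frames=stance_frames,
        contact_time=contact_time, approach_velocity=float(velocity),
        metrics=metrics_true)

    # --- observations
    markers = forward_markers(kin_true, model)
    if noise.marker_sd > 0:
        for name in markers.names:
            markers.markers[name] = (markers.markers[name]
                                     + rng_noise.normal(0.0, noise.marker_sd,
                                                        markers.markers[name].shape))
    fx_o, fy_o = fx_g, fy_g
    if noise.grf_sd > 0:
        fx_o = fx_g + rng_noise.normal(0.0, noise.grf_sd, fx_g.shape)
        fy_o = fy_g + rng_noise.normal(0.0, noise.grf_sd, fy_g.shape)
    grf_obs = GRFSeries(time=tg, fx=fx_o, fy=fy_o, cop_x=cop_g, rate=fs_g)

    trial = TrialTimeSeries(
        markers=markers, grf=grf_obs, body_mass=model.body_mass, height=model.height,
        meta={"limb": limb, "seed": int(seed), "velocity": float(velocity),
              "angle_peak": float(angle_peak), "quad_peak_bw": float(quad_peak_bw)})
    return trial, truth


def _so_single(m_row, kin, model, i):
    """Static optimization restricted to a single frame."""
    frames = np.array([i])
    kin1 = _slice_kin(kin, frames)
    mom = _moments_from(np.atleast_2d(m_row), kin1.time, None)
    return static_optimization(mom, kin1, model)


def _slice_kin(kin, frames):
    return kn.JointKinematics(
        time=kin.time[frames],
        angles={j: a[frames] for j, a in kin.angles.items()},
        angular_velocity={j: a[frames] for j, a in kin.angular_velocity.items()},
        angular_acceleration={j: a[frames] for j, a in kin.angular_acceleration.items()},
        pelvis=kin.pelvis[frames],
    )


def _moments_from(stacked, time, grf):
    from .dynamics import NetJointMoments
    stacked = np.atleast_2d(stacked)
    return NetJointMoments(
        time=np.asarray(time, dtype=float),
        moments={"hip": stacked[:, 0], "knee": stacked[:, 1], "ankle": stacked[:, 2]},
        grf=grf)
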