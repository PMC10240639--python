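"""Per-trial stance metrics and the between-limb mixed-effects comparison.

The comparison fits, per outcome,

    outcome ~ limb + approach_velocity + (1 | participant)

by REML on trial-level rows, reports velocity-adjusted marginal means per
limb (evaluated at the pooled mean approach velocity), and Tukey-adjusted
pairwise limb contrasts using the studentized range distribution.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import studentized_range, t as t_dist

from .errors import InputError, MetricsUnavailableError

LIMB_LEVELS = ("ACLR", "contralateral", "control")
OUTCOMES = ("peak_pfj_bw", "knee_angle_deg", "quad_force_bw")
METRIC_COLUMNS = ("participant_id", "limb", "trial",
                  "peak_pfj_bw", "knee_angle_deg", "quad_force_bw",
                  "approach_velocity_ms")


@dataclass
class StanceMetrics:
    """Scalar outcomes for one stance-phase trial."""

    participant_id: str
    limb: str
    trial: int
    peak_pfj: float            # BW
    angle_at_peak: float       # deg
    quad_at_peak: float        # BW
    approach_velocity: float   # m/s
    peak_time_pct: float       # % of stance
    flags: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.limb not in LIMB_LEVELS:
            raise InputError(f"limb must be one of {LIMB_LEVELS}, got {self.limb!r}")
        if self.peak_pfj < 0:
            raise InputError("peak PFJ force must be >= 0")
        if not 0.0 <= self.peak_time_pct <= 100.0:
            raise InputError("peak time must lie in [0, 100]% of stance")

    def as_row(self) -> dict:
        return {
            "participant_id": self.participant_id,
            "limb": self.limb,
            "trial": self.trial,
            "peak_pfj_bw": self.peak_pfj,
            "knee_angle_deg": self.angle_at_peak,
            "quad_force_bw": self.quad_at_peak,
            "approach_velocity_ms": self.approach_velocity,
            "peak_time_pct": self.peak_time_pct,
        }


def extract_metrics(pfj, kin, stance, velocity: float, *,
                    participant_id: str = "", limb: str = "ACLR", trial: int = 0,
                    exclude=None) -> StanceMetrics:
    """Peak PFJ force over stance plus angle/quadriceps force at that sample.

    ``stance`` is an index array (or slice) into the trial's sample axis.
    Ties take the earliest sample.  ``exclude`` masks flagged-infeasible
    samples; if everything in stance is excluded the trial has no metrics.
    """
    idx = np.arange(pfj.f_pfj.size)[stance]
    if idx.size == 0:
        raise InputError("stance interval is empty")
    if exclude is not None:
        idx = idx[~np.asarray(exclude, dtype=bool)[idx]]
    if idx.size == 0:
        raise MetricsUnavailableError("all stance frames are flagged")
    rel = int(np.argmax(pfj.f_pfj[idx]))   # argmax -> earliest on exact ties
    i_peak = int(idx[rel])
    full = np.arange(pfj.f_pfj.size)[stance]
    span = full[-1] - full[0]
    pct = 100.0 * (i_peak - full[0]) / span if span > 0 else 0.0
    return StanceMetrics(
        participant_id=participant_id, limb=limb, trial=trial,
        peak_pfj=float(pfj.f_pfj[i_peak]),
        angle_at_peak=float(kin.angles["knee"][i_peak]),
        quad_at_peak=float(pfj.f_q[i_peak]),
        approach_velocity=float(velocity),
        peak_time_pct=float(pct),
        flags={"clamped_at_peak": bool(pfj.clamped[i_peak]),
               "n_excluded": int(full.size - idx.size)},
    )


# ---------------------------------------------------------------------------
# mixed model


@dataclass
class LimbComparisonResult:
    """Velocity-adjusted limb comparison for one outcome."""

    outcome: str
    fixed_effects: dict[str, dict]        # name -> {estimate, se}
    velocity_slope: float
    velocity_slope_se: float
    marginal_means: dict[str, dict]       # limb -> {mean, se, ci_low, ci_high}
    pairwise: dict[str, dict]             # "A - B" -> {diff, se, ci, p_tukey}
    variance_participant: float
    residual_variance: float
    df: float
    pooled_velocity: float
    n_obs: int
    n_participants: int
    singular: bool = False
    diagnostics: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "outcome": self.outcome,
            "fixed_effects": self.fixed_effects,
            "velocity_slope": self.velocity_slope,
            "velocity_slope_se": self.velocity_slope_se,
            "marginal_means": self.marginal_means,
            "pairwise": self.pairwise,
            "variance_participant": self.variance_participant,
            "residual_variance": self.residual_variance,
            "df": self.df,
            "pooled_velocity": self.pooled_velocity,
            "n_obs": self.n_obs,
            "n_participants": self.n_participants,
            "singular": self.singular,
        }


def _validate_metrics_table(df: pd.DataFrame, outcome: str) -> pd.DataFrame:
    if df is None or len(df) == 0:
        raise InputError("metrics table is empty")
    needed = {"participant_id", "limb", "approach_velocity_ms", outcome}
    missing = needed - set(df.columns)
    if missing:
        raise InputError(f"metrics table missing columns: {sorted(missing)}")
    bad = set(df["limb"]) - set(LIMB_LEVELS)
    if bad:
        raise InputError(f"unknown limb labels: {sorted(bad)}")
    counts = df.groupby("limb")["participant_id"].nunique()
    low = counts[counts < 2]
    if len(low):
        raise InputError(
            f"need >= 2 participants per limb group; short: {dict(low)}")
    return df.reset_index(drop=True)


def fit_limb_model(metrics: pd.DataFrame, outcome: str) -> LimbComparisonResult:
    """REML mixed model with limb fixed effect and participant intercept.

    Marginal means are evaluated at the pooled mean approach velocity across
    all rows.  Degrees of freedom for CIs and Tukey tests use a
    between-within approximation (participants minus limb levels).  A
    boundary fit (zero participant variance) is reported with OLS fixed
    effects and ``singular=True`` rather than aborting.
    """
    import statsmodels.api as sm

    df = _validate_metrics_table(metrics, outcome)
    limbs = [lv for lv in LIMB_LEVELS if lv in set(df["limb"])]
    y = df[outcome].to_numpy(dtype=float)
    v = df["approach_velocity_ms"].to_numpy(dtype=float)
    v_bar = float(np.mean(v))

    # design: intercept = first limb level, treatment dummies for the rest
    X = np.column_stack(
        [np.ones(len(df))]
        + [(df["limb"] == lv).to_numpy(dtype=float) for lv in limbs[1:]]
        + [v])
    names = ["intercept"] + [f"limb[{lv}]" for lv in limbs[1:]] + ["approach_velocity_ms"]
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise InputError("rank-deficient design: limb or velocity columns are collinear")
    groups = df["participant_id"].to_numpy()

    singular = False
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = sm.MixedLM(y, X, groups=groups).fit(reml=True)
        var_b = float(np.asarray(fit.cov_re)[0, 0])
        var_e = float(fit.scale)
        if not (np.isfinite(var_b) and np.isfinite(var_e)):
            raise FloatingPointError("non-finite variance components")
    except (np.linalg.LinAlgError, ValueError, ZeroDivisionError, FloatingPointError):
        # degenerate data (e.g. zero residual variance); use the OLS limit
        var_b, var_e = 0.0, 0.0
    if var_b < 1e-8 * max(var_e, 1e-12):
        # boundary: the REML solution coincides with OLS; report it exactly
        singular = True
        ols = sm.OLS(y, X).fit()
        beta = np.asarray(ols.params, dtype=float)
        cov = np.asarray(ols.cov_params(), dtype=float)
        var_b = 0.0
        var_e = float(ols.scale)
    else:
        beta = np.asarray(fit.fe_params, dtype=float)
        cov = np.asarray(fit.cov_params())[:len(beta), :len(beta)]

    n_participants = int(df["participant_id"].nunique())
    dof = max(float(n_participants - len(limbs)), 1.0)
    tcrit = float(t_dist.ppf(0.975, dof))

    def contrast_row(limb):
        row = np.zeros(len(beta))
        row[0] = 1.0
        if limb != limbs[0]:
            row[1 + limbs[1:].index(limb)] = 1.0
        row[-1] = v_bar
        return row

    marginal = {}
    for lv in limbs:
        c = contrast_row(lv)
        mean = float(c @ beta)
        se = float(np.sqrt(c @ cov @ c))
        marginal[lv] = {"mean": mean, "se": se,
                        "ci_low": mean - tcrit * se, "ci_high": mean + tcrit * se}

    k = len(limbs)
    qcrit = float(studentized_range.ppf(0.95, k, dof)) if k > 1 else np.nan
    pairwise = {}
    for i in range(k):
        for j in range(i + 1, k):
            a, b = limbs[i], limbs[j]
            c = contrast_row(a) - contrast_row(b)
            diff = float(c @ beta)
            se = float(np.sqrt(c @ cov @ c))
            qstat = abs(diff) / se * np.sqrt(2.0) if se > 0 else np.inf
            p = float(studentized_range.sf(qstat, k, dof))
            half = qcrit / np.sqrt(2.0) * se
            pairwise[f"{a} - {b}"] = {
                "diff": diff, "se": se,
                "ci_low": diff - half, "ci_high": diff + half,
                "p_tukey": p,
            }

    return LimbComparisonResult(
        outcome=outcome,
        fixed_effects={nm: {"estimate": float(b), "se": float(np.sqrt(cov[i, i]))}
                       for i, (nm, b) in enumerate(zip(names, beta))},
        velocity_slope=float(beta[-1]),
        velocity_slope_se=float(np.sqrt(cov[-1, -1])),
        marginal_means=marginal,
        pairwise=pairwise,
        variance_participant=var_b,
        residual_variance=var_e,
        df=dof,
        pooled_velocity=v_bar,
        n_obs=len(df),
        n_participants=n_participants,
        singular=singular,
    )


def compare_all(metrics: pd.DataFrame,
                outcomes=OUTCOMES) -> dict[str, LimbComparisonResult]:
    """Fit the limb model for each outcome; raises on an empty table."""
    if metrics is None or len(metrics) == 0:
        raise InputError("metrics table is empty")
    return {out: fit_limb_model(metrics, out) for out in outcomes}


def summary_table(results: dict[str, LimbComparisonResult]) -> str:
    """Render a limbs x outcomes marginal-mean table (mean and 95% CI)."""
    headers = {"peak_pfj_bw": "Peak PFJ Force, BW",
               "knee_angle_deg": "Knee Flexion Angle, deg",
               "quad_force_bw": "Quadriceps Force, BW"}
    outs = list(results)
    lines = ["limb" + "".join(f"\t{headers.get(o, o)}" for o in outs)]
    limbs = list(next(iter(results.values())).marginal_means)
    for lv in limbs:
        cells = []
        for o in outs:
            mm = results[o].marginal_means[lv]
            cells.append(f"{mm['mean']:.1f} ({mm['ci_low']:.1f}-{mm['ci_high']:.1f})")
        lines.append(lv + "".join(f"\t{c}" for c in cells))
    return "\n".join(lines)


def descriptive_diagnostics(metrics: pd.DataFrame, outcome: str) -> dict:
    """Optional descriptives: per-limb Shapiro-Wilk and a two-group t test."""
    from scipy import stats

    df = _validate_metrics_table(metrics, outcome)
    out = {"outcome": outcome, "shapiro": {}, "ttest_aclr_vs_control": None}
    for lv, sub in df.groupby("limb"):
        vals = sub[outcome].to_numpy(dtype=float)
        if vals.size >= 3:
            w, p = stats.shapiro(vals)
            out["shapiro"][lv] = {"W": float(w), "p": float(p)}
    a = df.loc[df["limb"] == "ACLR", outcome]
    c = df.loc[df["limb"] == "control", outcome]
    if len(a) > 1 and len(c) > 1:
        t, p = stats.ttest_ind(a, c)
        out["ttest_aclr_vs_control"] = {"t": float(t), "p": float(p)}
    return out
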