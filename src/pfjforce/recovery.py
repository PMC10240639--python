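"""Parameter-recovery simulations against the shipped cohort calibration.

These drive the headline verification of the pipeline: generate cohorts
from the versioned defaults, push them through the mixed-model comparison,
and report how well the velocity-adjusted marginal means and the
approach-velocity rule recover the calibration values.
"""

from __future__ import annotations

import numpy as np

from .kinematics import approach_velocity, detect_stance, inverse_kinematics
from .metrics_stats import LIMB_LEVELS, OUTCOMES, fit_limb_model
from .synthetic_cohort import CohortDesign, NoiseSpec, generate_metric_cohort, generate_signal_trial


def marginal_mean_recovery(design: CohortDesign, seeds) -> dict:
    """Replicate the metric-level cohort and average marginal means.

    Returns per outcome and limb the replicate mean, the Monte-Carlo
    standard error of that mean, and the calibration target.
    """
    seeds = list(seeds)
    estimates = {o: {l: [] for l in LIMB_LEVELS} for o in OUTCOMES}
    for seed in seeds:
        df = generate_metric_cohort(design, seed)
        for outcome in OUTCOMES:
            res = fit_limb_model(df, outcome)
            for limb in LIMB_LEVELS:
                estimates[outcome][limb].append(res.marginal_means[limb]["mean"])
    out = {}
    for outcome in OUTCOMES:
        out[outcome] = {}
        for limb in LIMB_LEVELS:
            vals = np.asarray(estimates[outcome][limb])
            out[outcome][limb] = {
                "mean": float(vals.mean()),
                "mc_se": float(vals.std(ddof=1) / np.sqrt(vals.size)),
                "target": float(design.limbs[limb].mu[outcome]),
                "n_replicates": int(vals.size),
            }
    return out


def approach_velocity_recovery(design: CohortDesign, n_trials: int, seed: int,
                               model=None, limb: str = "ACLR",
                               marker_noise_sd: float = 0.002) -> dict:
    """Signal-level trials -> 20 N contact rule -> 50 ms COM velocity rule.

    Each trial draws its pre-contact velocity from the limb's calibrated
    distribution; the velocity is then re-measured from the generated
    markers and force record exactly as the pipeline would.
    """
    from .model import PlanarModel

    if model is None:
        model = PlanarModel.from_yaml()
    noise = NoiseSpec(marker_sd=marker_noise_sd)
    measured, drawn = [], []
    base = np.random.SeedSequence([int(seed), 0xA77])
    trial_seeds = base.generate_state(n_trials)
    for s in trial_seeds:
        trial, truth = generate_signal_trial(design, limb, noise, int(s), model)
        i0, _ = detect_stance(trial.grf.fy, 20.0)
        contact_time = float(trial.grf.time[i0])
        # unfiltered markers: the zero-lag low-pass is non-causal and leaks
        # stance motion into the pre-contact window; the velocity rule is a
        # position difference, so it needs no smoothing
        kin = inverse_kinematics(trial.markers, model)
        com_x = model.com(kin.pose_trajectory())[:, 0]
        measured.append(approach_velocity(kin.time, com_x, contact_time, 0.050))
        drawn.append(truth.approach_velocity)
    measured = np.asarray(measured)
    return {
        "mean": float(measured.mean()),
        "mc_se": float(measured.std(ddof=1) / np.sqrt(n_trials)),
        "target": float(design.limbs[limb].velocity_mean),
        "mean_drawn": float(np.mean(drawn)),
        "n_trials": int(n_trials),
    }
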