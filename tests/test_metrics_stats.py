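import numpy as np
import pandas as pd
import pytest

from pfjforce.errors import InputError, MetricsUnavailableError
from pfjforce.kinematics import JointKinematics
from pfjforce.metrics_stats import (
    StanceMetrics,
    compare_all,
    descriptive_diagnostics,
    extract_metrics,
    fit_limb_model,
    summary_table,
)
from pfjforce.pfj_model import PFJForceSeries


def _series(f_pfj, theta=None):
    f_pfj = np.asarray(f_pfj, dtype=float)
    n = f_pfj.size
    t = np.arange(n) / 250.0
    theta = np.full(n, 45.0) if theta is None else np.asarray(theta, dtype=float)
    pfj = PFJForceSeries(time=t, f_q=0.8 * f_pfj, f_p=0.6 * f_pfj,
                         beta=np.full(n, 100.0), f_pfj=f_pfj,
                         clamped=np.zeros(n, dtype=bool))
    q = np.column_stack([np.zeros(n), np.ones(n), np.zeros(n), theta, np.zeros(n)])
    kin = JointKinematics.from_pose_trajectory(t, q)
    return pfj, kin


class TestExtractMetrics:
    def test_monotone_series_peaks_at_end(self):
        pfj, kin = _series(np.linspace(1, 10, 20))
        met = extract_metrics(pfj, kin, np.arange(20), 3.5)
        assert met.peak_pfj == 10.0
        assert met.peak_time_pct == 100.0

    def test_tie_takes_earliest(self):
        f = np.array([1.0, 5.0, 3.0, 5.0, 2.0])
        pfj, kin = _series(f, theta=np.array([10, 20, 30, 40, 50.0]))
        met = extract_metrics(pfj, kin, np.arange(5), 3.5)
        assert met.peak_time_pct == pytest.approx(25.0)
        assert met.angle_at_peak == 20.0

    def test_values_read_at_peak_sample(self):
        f = np.array([1.0, 2.0, 9.0, 4.0])
        pfj, kin = _series(f, theta=np.array([30, 40, 55, 35.0]))
        met = extract_metrics(pfj, kin, np.arange(4), 4.1, limb="control")
        assert met.angle_at_peak == 55.0
        assert met.quad_at_peak == pytest.approx(0.8 * 9.0)
        assert met.approach_velocity == 4.1

    def test_flagged_frames_excluded_from_peak(self):
        f = np.array([1.0, 99.0, 3.0, 4.0])
        pfj, kin = _series(f)
        met = extract_metrics(pfj, kin, np.arange(4), 3.5,
                              exclude=np.array([False, True, False, False]))
        assert met.peak_pfj == 4.0

    def test_all_flagged_raises(self):
        pfj, kin = _series([1.0, 2.0])
        with pytest.raises(MetricsUnavailableError):
            extract_metrics(pfj, kin, np.arange(2), 3.5, exclude=np.array([True, True]))

    def test_empty_stance_raises(self):
        pfj, kin = _series([1.0, 2.0])
        with pytest.raises(InputError):
            extract_metrics(pfj, kin, np.array([], dtype=int), 3.5)

    def test_unknown_limb_label_rejected(self):
        with pytest.raises(InputError):
            StanceMetrics(participant_id="x", limb="left", trial=1, peak_pfj=1.0,
                          angle_at_peak=10.0, quad_at_peak=1.0,
                          approach_velocity=3.0, peak_time_pct=50.0)


def _balanced_table(mus, n_per_group=6, trials=3, sd=0.0, slope=0.0, seed=0):
    rng = np.random.default_rng(seed)
    rows = []
    for gi, (limb, mu) in enumerate(mus.items()):
        for p in range(n_per_group):
            pid = f"{limb[:2]}{p:02d}"
            b = rng.normal(0, sd)
            for tr in range(trials):
                v = rng.normal(4.0, 0.4)
                rows.append({"participant_id": pid, "limb": limb, "trial": tr + 1,
                             "approach_velocity_ms": v,
                             "peak_pfj_bw": mu + b + slope * (v - 4.0),
                             "knee_angle_deg": 50.0, "quad_force_bw": 10.0})
    return pd.DataFrame(rows)


class TestFitLimbModel:
    def test_degenerate_no_noise_recovers_group_constants(self):
        df = _balanced_table({"ACLR": 10.0, "contralateral": 14.0, "control": 13.0})
        res = fit_limb_model(df, "peak_pfj_bw")
        assert res.singular  # zero between-participant variance
        assert res.marginal_means["ACLR"]["mean"] == pytest.approx(10.0, abs=1e-8)
        assert res.marginal_means["contralateral"]["mean"] == pytest.approx(14.0, abs=1e-8)
        assert res.marginal_means["control"]["mean"] == pytest.approx(13.0, abs=1e-8)
        assert all(p["p_tukey"] < 1e-6 for p in res.pairwise.values())

    def test_pairwise_differences_equal_marginal_mean_differences(self, design):
        from pfjforce.synthetic_cohort import generate_metric_cohort

        df = generate_metric_cohort(design, 17)
        res = fit_limb_model(df, "peak_pfj_bw")
        mm = res.marginal_means
        for key, pw in res.pairwise.items():
            a, b = key.split(" - ")
            assert pw["diff"] == pytest.approx(mm[a]["mean"] - mm[b]["mean"], abs=1e-10)

    def test_velocity_slope_recovered(self, design):
        """Estimated slope within 3 MC SEs of the generating slope at n=500."""
        import copy

        from pfjforce.synthetic_cohort import generate_metric_cohort

        d = copy.deepcopy(design)
        d.n_aclr, d.n_control = 500, 2
        df = generate_metric_cohort(d, 23)
        res = fit_limb_model(df, "peak_pfj_bw")
        assert abs(res.velocity_slope - 1.5) < 3 * res.velocity_slope_se

    def test_velocity_adjustment_removes_confounding(self, design):
        """With group-confounded velocities the adjusted means recover the
        calibration while raw group means do not (bias cut by >= 75%)."""
        import copy

        from pfjforce.synthetic_cohort import generate_metric_cohort

        d = copy.deepcopy(design)
        d.n_aclr, d.n_control = 200, 200
        adj_bias, raw_bias = [], []
        for seed in range(30):
            df = generate_metric_cohort(d, seed)
            res = fit_limb_model(df, "peak_pfj_bw")
            vbar = df.approach_velocity_ms.mean()
            for limb in ("ACLR", "contralateral", "control"):
                cal = d.limbs[limb]
                truth = cal.mu["peak_pfj_bw"]
                adj_bias.append(res.marginal_means[limb]["mean"] - truth)
                raw_bias.append(df.loc[df.limb == limb, "peak_pfj_bw"].mean() - truth)
        adj = np.mean(np.abs(np.asarray(adj_bias).reshape(-1, 3).mean(axis=0)))
        raw = np.mean(np.abs(np.asarray(raw_bias).reshape(-1, 3).mean(axis=0)))
        assert raw > 0.2  # velocity confounding biases raw means materially
        assert adj < 0.25 * raw

    def test_type_one_error_controlled_for_identical_groups(self, design):
        """Two identically generated groups: Tukey p > 0.05 in >= 90% of reps."""
        import copy

        from pfjforce.synthetic_cohort import generate_metric_cohort

        d = copy.deepcopy(design)
        d.n_aclr, d.n_control = 200, 2
        cal = d.limbs["ACLR"]
        d.limbs["contralateral"] = copy.deepcopy(cal)  # identical calibration
        hits = 0
        n_rep = 100
        for seed in range(n_rep):
            df = generate_metric_cohort(d, seed)
            df = df[df.limb.isin(["ACLR", "contralateral"])]
            res = fit_limb_model(df, "peak_pfj_bw")
            if res.pairwise["ACLR - contralateral"]["p_tukey"] > 0.05:
                hits += 1
        assert hits >= 90

    def test_single_trial_no_random_variance_matches_ols(self):
        import statsmodels.api as sm

        df = _balanced_table({"ACLR": 10.0, "contralateral": 14.0, "control": 13.0},
                             n_per_group=20, trials=1, sd=0.0, slope=1.2, seed=3)
        rng = np.random.default_rng(8)
        df["peak_pfj_bw"] += rng.normal(0, 0.5, len(df))  # pure residual noise
        res = fit_limb_model(df, "peak_pfj_bw")
        limbs = ["ACLR", "contralateral", "control"]
        X = np.column_stack([np.ones(len(df))]
                            + [(df.limb == l).to_numpy(float) for l in limbs[1:]]
                            + [df.approach_velocity_ms.to_numpy()])
        ols = sm.OLS(df.peak_pfj_bw.to_numpy(), X).fit()
        vbar = df.approach_velocity_ms.mean()
        for i, limb in enumerate(limbs):
            expected = ols.params[0] + (ols.params[i] if i else 0.0) + ols.params[-1] * vbar
            assert res.marginal_means[limb]["mean"] == pytest.approx(expected, abs=1e-8)

    def test_ci_widens_with_residual_variance(self):
        widths = []
        for noise_sd in (0.2, 1.0, 3.0):
            df = _balanced_table({"ACLR": 10.0, "contralateral": 14.0, "control": 13.0},
                                 n_per_group=10, trials=3, sd=0.0, seed=5)
            rng = np.random.default_rng(11)
            df["peak_pfj_bw"] += rng.normal(0, noise_sd, len(df))
            res = fit_limb_model(df, "peak_pfj_bw")
            mm = res.marginal_means["ACLR"]
            widths.append(mm["ci_high"] - mm["ci_low"])
        assert widths[0] < widths[1] < widths[2]

    def test_too_few_participants_rejected(self):
        df = _balanced_table({"ACLR": 10.0, "contralateral": 14.0, "control": 13.0},
                             n_per_group=1)
        with pytest.raises(InputError):
            fit_limb_model(df, "peak_pfj_bw")

    def test_missing_outcome_rejected(self, design):
        from pfjforce.synthetic_cohort import generate_metric_cohort

        df = generate_metric_cohort(design, 1)
        with pytest.raises(InputError):
            fit_limb_model(df, "nonexistent_metric")


class TestCompareAll:
    def test_empty_table_rejected(self):
        with pytest.raises(InputError):
            compare_all(pd.DataFrame())

    def test_single_outcome_bundle(self, design):
        from pfjforce.synthetic_cohort import generate_metric_cohort

        df = generate_metric_cohort(design, 2)
        bundle = compare_all(df, outcomes=["quad_force_bw"])
        assert list(bundle) == ["quad_force_bw"]

    def test_default_cohort_three_by_three_structure(self, design):
        from pfjforce.synthetic_cohort import generate_metric_cohort

        df = generate_metric_cohort(design, 4)
        bundle = compare_all(df)
        assert set(bundle) == {"peak_pfj_bw", "knee_angle_deg", "quad_force_bw"}
        for res in bundle.values():
            assert set(res.marginal_means) == {"ACLR", "contralateral", "control"}
            assert len(res.pairwise) == 3
        table = summary_table(bundle)
        assert table.count("\n") == 3  # header + three limb rows

    def test_diagnostics_smoke(self, design):
        from pfjforce.synthetic_cohort import generate_metric_cohort

        df = generate_metric_cohort(design, 6)
        out = descriptive_diagnostics(df, "peak_pfj_bw")
        assert set(out["shapiro"]) == {"ACLR", "contralateral", "control"}
        assert 0.0 <= out["ttest_aclr_vs_control"]["p"] <= 1.0
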