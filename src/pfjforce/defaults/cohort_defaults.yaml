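# Default synthetic-cohort calibration.
#
# Group means (mu) are the published velocity-adjusted marginal means for
# peak PFJ contact force (BW), knee flexion angle at peak (deg) and
# quadriceps force at peak (BW), per limb; velocity means/SDs are the
# published per-limb approach velocities (m/s).
#
# Between-participant SDs are back-calculated from the printed 95% CI
# half-widths h of the marginal means: h ~= t(0.975, df) * SE with
# SE^2 ~= (sd_between^2 + sd_within^2 / trials) / n.  With n = 26 (ACLR)
# or 22 (control), 3 trials, and h ~ 1.4 BW / 2.5 deg / 0.85 BW this gives
# sd_between ~ 3.4 BW / 6.2 deg / 2.1 BW.  Within-participant trial SDs are
# NOT reported anywhere in the source material; the values here are
# assumptions chosen at roughly one third of the between-participant SD.
#
# velocity_slope values (outcome units per m/s) are likewise assumptions:
# large enough that velocity adjustment is exercised, small enough not to
# dominate group effects.
version: 1
n_aclr: 26
n_control: 22
trials_per_limb: 3
metrics: [peak_pfj_bw, knee_angle_deg, quad_force_bw]
limbs:
  ACLR:
    mu: {peak_pfj_bw: 12.7, knee_angle_deg: 52.0, quad_force_bw: 10.9}
    sd_between: {peak_pfj_bw: 3.4, knee_angle_deg: 6.2, quad_force_bw: 2.1}
    sd_within: {peak_pfj_bw: 1.2, knee_angle_deg: 2.0, quad_force_bw: 0.8}
    velocity: {mean: 3.7, sd: 0.6}
  contralateral:
    mu: {peak_pfj_bw: 18.7, knee_angle_deg: 56.0, quad_force_bw: 15.1}
    sd_between: {peak_pfj_bw: 3.4, knee_angle_deg: 6.2, quad_force_bw: 2.1}
    sd_within: {peak_pfj_bw: 1.2, knee_angle_deg: 2.0, quad_force_bw: 0.8}
    velocity: {mean: 3.9, sd: 0.5}
  control:
    mu: {peak_pfj_bw: 17.1, knee_angle_deg: 57.0, quad_force_bw: 13.7}
    sd_between: {peak_pfj_bw: 3.4, knee_angle_deg: 6.2, quad_force_bw: 2.1}
    sd_within: {peak_pfj_bw: 1.2, knee_angle_deg: 2.0, quad_force_bw: 0.8}
    velocity: {mean: 4.3, sd: 0.6}
velocity_slope: {peak_pfj_bw: 1.5, knee_angle_deg: 1.0, quad_force_bw: 1.0}
# Within-trial correlation among (peak_pfj_bw, knee_angle_deg, quad_force_bw):
# angle and quadriceps force each correlated 0.5 with peak PFJ force.
metric_correlation:
  - [1.00, 0.50, 0.50]
  - [0.50, 1.00, 0.25]
  - [0.50, 0.25, 1.00]
# Signal-level trial shape parameters.
signal:
  stance_duration_s: 0.25
  precontact_duration_s: 0.12
  marker_rate_hz: 250.0
  grf_rate_hz: 1000.0
  peak_fraction_of_stance: 0.45
  knee_angle_at_contact_deg: 22.0
  hip_angle_at_contact_deg: 30.0
  hip_angle_peak_deg: 50.0
  velocity_loss_fraction: 0.35
  hip_demand_ratio: -0.4
  ankle_demand_ratio: 0.5
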