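# pfjforce

A planar (sagittal-plane) musculoskeletal analysis pipeline for
patellofemoral joint (PFJ) contact force during stance-phase cutting
trials, together with a calibrated synthetic-cohort generator and a
mixed-effects between-limb comparison.

The pipeline chains:

1. **Inverse kinematics** — weighted least-squares fit of a four-segment
   planar chain (pelvis–thigh–shank–foot) to marker trajectories.
2. **Inverse dynamics** — bottom-up Newton–Euler net joint moments from
   kinematics and ground-reaction force.
3. **Static optimization** — frame-by-frame decomposition of net moments
   into eight lumped muscle forces, minimizing the sum of squared
   activations under moment-equality and activation-bound constraints.
4. **PFJ contact force** — law-of-cosines resultant of the quadriceps- and
   patellar-tendon forces, with the tendon force ratio `k(θ)` and mechanism
   angle `β(θ)` as configurable polynomials of knee flexion.
5. **Metrics & statistics** — peak PFJ force per stance (20 N rule), knee
   flexion angle and quadriceps force at that peak, approach velocity
   (mean forward COM velocity in the 50 ms before contact), and a
   REML mixed model `outcome ~ limb + velocity + (1 | participant)` with
   velocity-adjusted marginal means and Tukey-adjusted pairwise contrasts.

Because no raw motion-capture data accompany the analysis, the
`synthetic_cohort` module generates trials at two fidelity levels:

* **metric level** — scalar outcomes per trial with participant random
  intercepts, calibrated to published group marginal means
  (defaults in `src/pfjforce/defaults/cohort_defaults.yaml`);
* **signal level** — full marker/GRF time series whose ground reaction is
  solved by inverting the planar dynamics for designed joint-moment
  curves, so a noiseless pipeline run reproduces its own ground truth.

All defaults (planar model, patellar mechanism, cohort calibration) are
versioned YAML files under `src/pfjforce/defaults/`.

## CLI

```sh
pfjforce simulate --seed 1 --out sim/              # metric-level cohort CSV
pfjforce simulate --seed 1 --out sim/ --level signal --n-signal-trials 6
pfjforce run-all --input sim/ --out results/       # full pipeline over trials
pfjforce ik --markers trial_markers.trc --out angles.mot
pfjforce events --grf trial_grf.mot --threshold 20
pfjforce id --angles angles.mot --grf trial_grf.mot --out moments.sto
pfjforce so --moments moments.sto --angles angles.mot --out forces.sto
pfjforce pfj --fq forces.sto --angles angles.mot --out pfj.sto
pfjforce stats --metrics metrics.csv --outcome all --out stats/
pfjforce diagnostics --metrics metrics.csv
```

## Layout

```
src/pfjforce/
  kinematics.py        IK, stance events, approach velocity, normalization
  dynamics.py          Newton-Euler inverse dynamics (+ inversion helper)
  muscle_forces.py     static optimization (active-set QP)
  pfj_model.py         patellar mechanism and contact-force model
  metrics_stats.py     stance metrics, mixed model, Tukey contrasts
  synthetic_cohort.py  metric- and signal-level generators
  recovery.py          parameter-recovery simulations
  io_cli.py            TRC/MOT/CSV/JSON formats, pipeline, click CLI
  model.py             planar model, scaling, forward kinematics
  defaults/            versioned model/mechanism/cohort defaults (YAML)
```
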