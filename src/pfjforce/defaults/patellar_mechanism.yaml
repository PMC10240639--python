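# Patellar mechanism defaults.
#
# k(theta): patellar-tendon / quadriceps-tendon force ratio, dimensionless,
#           polynomial in knee flexion angle theta (degrees, ascending powers).
# beta(theta): angle (degrees) between the quadriceps-tendon and
#           patellar-tendon force directions acting on the patella.
#
# The published in vitro source curves for these two functions are not
# reprinted anywhere in machine-readable form; these coefficients are a
# smooth fit reproducing the qualitative shape of the published cadaveric
# data (ratio ~1 near extension falling with flexion; mechanism angle
# shrinking with flexion so the resultant compression grows).  Every result
# produced with this file records its version so the mechanism is swappable.
version: 1
k_coeffs: [1.05, -0.0055, 1.0e-5]
beta_coeffs: [150.0, -0.95]
valid_range_deg: [0.0, 120.0]
provenance: >
  Synthetic polynomial fit to the shape of published in vitro
  patellofemoral mechanics curves; not the original authors' coefficients.
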