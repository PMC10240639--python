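# Default planar (sagittal) four-segment lower-limb model.
#
# Segment mass/length/inertia proportions follow standard published
# anthropometric proportion tables (Winter-style fractions). The pelvis
# segment lumps everything proximal to the analyzed leg (head, arms, trunk,
# pelvis, swing leg), so segment mass fractions sum to 1.
#
# Marker offsets are expressed as fractions of the owning segment's length,
# in the segment-local frame: +x forward at the reference pose, -y down the
# segment axis (pelvis/thigh/shank) or along the sole (foot).
#
# Moment-arm polynomials are in metres, ascending powers of the spanned
# joint's angle in degrees.  Sign conventions: hip flexion positive, knee
# extension positive, ankle plantarflexion positive.
version: 1
reference:
  body_mass_kg: 75.0
  height_m: 1.75
gravity: 9.81
ankle_height_frac: 0.039        # ankle joint centre height / body height
segments:
  pelvis:
    length_frac_height: 0.100
    mass_frac: 0.8390
    com_offset: [0.0, 0.30]
    gyration_frac: 0.35
  thigh:
    length_frac_height: 0.245
    mass_frac: 0.1000
    com_offset: [0.0, -0.433]
    gyration_frac: 0.323
  shank:
    length_frac_height: 0.246
    mass_frac: 0.0465
    com_offset: [0.0, -0.433]
    gyration_frac: 0.302
  foot:
    length_frac_height: 0.152
    mass_frac: 0.0145
    com_offset: [0.35, -0.15]
    gyration_frac: 0.475
markers:
  SACR: {segment: pelvis, offset: [-1.20, 0.30], weight: 1.0}
  PELF: {segment: pelvis, offset: [0.90, 0.30], weight: 1.0}
  THI1: {segment: thigh, offset: [0.12, -0.25], weight: 1.0}
  THI2: {segment: thigh, offset: [0.10, -0.70], weight: 1.0}
  SHA1: {segment: shank, offset: [0.10, -0.30], weight: 1.0}
  SHA2: {segment: shank, offset: [0.08, -0.72], weight: 1.0}
  HEEL: {segment: foot, offset: [-0.25, -0.20], weight: 1.0}
  MET:  {segment: foot, offset: [0.45, -0.10], weight: 1.0}
  TOE:  {segment: foot, offset: [0.80, -0.20], weight: 1.0}
muscles:
  iliopsoas:
    f_max: 3000.0
    group: flexor
    quadriceps: false
    arms:
      hip: [0.050]
  gluteus_maximus:
    f_max: 6000.0
    group: extensor
    quadriceps: false
    arms:
      hip: [-0.062]
  hamstrings:
    f_max: 5000.0
    group: extensor
    quadriceps: false
    arms:
      hip: [-0.060]
      knee: [-0.030]
  rectus_femoris:
    f_max: 3500.0
    group: extensor
    quadriceps: true
    arms:
      hip: [0.042]
      knee: [0.048, -1.0e-4]
  vasti:
    f_max: 14000.0
    group: extensor
    quadriceps: true
    arms:
      knee: [0.048, -1.0e-4]
  gastrocnemius:
    f_max: 4000.0
    group: flexor
    quadriceps: false
    arms:
      knee: [-0.020]
      ankle: [0.052]
  soleus:
    f_max: 8000.0
    group: extensor
    quadriceps: false
    arms:
      ankle: [0.052]
  tibialis_anterior:
    f_max: 1500.0
    group: flexor
    quadriceps: false
    arms:
      ankle: [-0.040]
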