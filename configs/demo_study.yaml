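# Demo study: all four report tables from synthetic data in one run.
# Conditions mirror the reference study designs: three-drug fixed-ratio
# plates, an engraftment cohort with control/single/combination arms, and a
# sparse destructively-sampled PK study with a clearance effect in the
# combination arm.
seed: 20120329

invitro:
  truth:
    m: {VCR: 1.2, DEX: 0.9, ASP: 1.0}
    dm: {VCR: 1.5, DEX: 180.0, ASP: 3.0}     # ng/mL, nM, U/mL
    ratio: {VCR: 0.5, DEX: 50.0, ASP: 1.0}
    phi: 0.25
    noise_sd: 0.10
    n_reps: 12
  dose_levels: [1.0, 2.5, 5.0, 10.0]

invivo:
  truth:
    g: 0.1
    f0: 1.0
    kills: {VCR: 0.055, DEX: 0.012, ASP: 0.012}
    k_int: 0.02
    noise_sd: 0.15
    cv_g: 0.15
    cv_f0: 0.25
    morbidity_hazard: 0.001
  arms:
    control: []
    VCR: [VCR]
    DEX: [DEX]
    ASP: [ASP]
    VXL: [VCR, DEX, ASP]
  n_mice: 8
  followup: 160.0
  control_arm: control
  combination_arm: VXL
  single_arms: [VCR, DEX, ASP]

pk:
  truth:
    n_compartments: 1
    ka: 25.0
    cl: 1525.0        # mL/h/kg  (DEX-like: 5 mg/kg -> AUC ~3.3 ug*h/mL)
    v: 2800.0         # mL/kg
    dose: 5.0e+6      # ng/kg
    theta_cl: 0.48
    prop_sd: 0.15
  multistart: 10

stratification:
  source: bundled
  cutoff: 55.0
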