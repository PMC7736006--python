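# Default run configuration.
#
# Units: clearances L/h, volumes L, rates 1/h, times h, concentrations mg/L,
# doses mg.  IIV entries are variances of log-scale random effects.
#
# The plasma parameter sets below are ILLUSTRATIVE two-compartment values
# typical of critically-ill piperacillin kinetics.  The brain model is driven
# by unbound plasma concentrations (FU fixed at 0.70); plasma parameters are
# always fixed, never estimated.  The wide clearance variability reflects the
# broad renal-function range of intensive-care cohorts.

plasma:
  default:
    CL: 14.0
    Q: 15.0
    Vc: 12.0
    Vp: 10.0
    FU: 0.70
    iiv:            # log-variance; CL ~ CV 55%, volumes ~ CV 30%
      CL: 0.2643
      Vc: 0.0862
      Vp: 0.0862
  # alternative illustrative sets for the plasma-model sensitivity hook
  alt_a:
    CL: 16.0
    Q: 12.0
    Vc: 10.0
    Vp: 8.0
    FU: 0.70
    iiv: {CL: 0.2643, Vc: 0.0862, Vp: 0.0862}
  alt_b:
    CL: 11.0
    Q: 20.0
    Vc: 15.0
    Vp: 12.0
    FU: 0.70
    iiv: {CL: 0.2643, Vc: 0.0862, Vp: 0.0862}

# Simulation truth / reference values for the brain ECF model
# (bootstrap medians of the fitted study model).
brain:
  K_pb: 0.32        # plasma -> brain transfer rate, 1/h
  K_bp_fd: 7.31     # brain -> plasma rate after first dose, 1/h
  K_bp_md: 4.39     # brain -> plasma rate after multiple doses, 1/h
  T_lag_fd: 2.70    # input lag after first dose, h
  T_lag_md: 0.0     # fixed
  omega_tlag: 0.0380757   # log-variance of IIV on T_lag (CV 19.7%)
  sigma_add: 0.03   # additive residual SD, mg/L
  sigma_prop: 0.35  # proportional residual SD, fraction

# Generic initial estimates for fitting (deliberately away from the truth).
init:
  K_pb: 0.5
  K_bp_fd: 5.0
  K_bp_md: 5.0
  T_lag_fd: 2.0
  T_lag_md: 0.0
  omega_tlag: 0.05
  sigma_add: 0.05
  sigma_prop: 0.30

design:
  n_subjects: 10
  dose_mg: 4000.0
  tau_h: 8.0
  t_inf_h: 0.5
  samples_per_occasion: 7
  lloq: 0.05
  ss_dose_number: 15     # steady-state occasion around dose 15 (day 5)
  catheter:
    dead_volume_ul: 5.1
    flow_rate_ul_min: 0.3
    recovery: 1.0

pta:
  n_subjects: 5000
  target_pct: 50.0
  daily_doses_g: [12, 16, 24]
  modes: [intermittent, extended, continuous]
  extended_hours: 3.0    # 4.0 is the alternative
  mic_grid: [0.0625, 0.125, 0.25, 0.5, 1, 2, 4, 8, 16]
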