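# cvrkit run configuration.
# Protocol blocks mirror the acquisition protocol card (ms / uT / mT/m / cm/s).

protocols:
  single_pld_pcasl:
    technique: single_pld_pcasl
    labeling_pulse_shape: hanning
    labeling_pulse_duration_ms: 0.5
    labeling_pulse_spacing_ms: 1.22
    mean_b1_ut: 1.4
    mean_gradient_strength_mt_m: 0.7
    maximal_gradient_strength_mt_m: 7.0
    bolus_duration_ms: 1450
    pld_ms: [2025]
    tr_ms: 4854
  multi_pld_pcasl:
    technique: multi_pld_pcasl
    labeling_pulse_shape: hanning
    labeling_pulse_duration_ms: 0.5
    labeling_pulse_spacing_ms: 1.22
    mean_b1_ut: 1.8
    mean_gradient_strength_mt_m: 0.7
    maximal_gradient_strength_mt_m: 4.5
    bolus_duration_ms: 1700
    pld_ms: [300, 2000, 3700]
    tr_ms: 5652
  vsasl:
    technique: vsasl
    bolus_duration_ms: 1590
    inversion_time_ms: 1600
    vc_cm_s: 2
    tr_ms: 4064
    labeling_efficiency: 0.9

quantification:
  t1_tissue_s: 1.3
  partition_coefficient: 0.9
  pd_reference_tr_ms: 2000
  m0_erosion_radius: 1
  att_prior_mean_s: 1.3
  att_prior_sd_s: 1.0
  spatial_iterations: 1

experiment:
  # experiment1: consensus alpha/T1b for every subject;
  # experiment2: per-subject estimated alpha (Bloch + vessel flow weighting)
  # and T1b from hematocrit.
  consensus_alpha: 0.85
  consensus_t1_blood_s: 1.65
  acquisition_efficiency_mode: simulated   # fixed | simulated
  bloch_time_step_ms: 0.02
  noiseless: false

blood:
  # 3 T arterial relaxometry coefficients (s^-1); see cvrkit.blood
  t1_hct_slope: 0.4055
  t1_intercept: 0.3955
  t1_deoxy_coef: 1.1

phantom:
  grid_shape: [32, 32, 24]
  voxel_size: [4.0, 4.0, 4.0]
  n_subjects: 8
  gm: {cbf_pre: 60.0, cvr_true: 42.0, att_pre: 1.2}
  wm: {cbf_pre: 22.0, cvr_true: 38.0, att_pre: 1.45, m0_tissue: 850.0, lambda_p: 0.82}
  csf: {cbf_pre: 0.0, cvr_true: 0.0, att_pre: 1.2, m0_tissue: 1300.0, lambda_p: 0.3}
  att_reduction: 0.10
  asl_temporal_snr: 20.0
  pet_noise_scale: 1.0
  vessel_velocity_pre: 27.0
  vessel_velocity_post: 38.0
  hematocrit_mean: 0.43
  hematocrit_sd: 0.05

pet:
  frame_blocks: [[30, 1], [10, 3], [12, 5], [12, 10], [12, 30]]
  lambda_bounds: [0.3, 1.2]
  median_filter_window: 5

stats:
  n_permutations: 500
  smoothing_fwhm_mm: 3.0
  robust_lo_pct: 1.0
  robust_hi_pct: 99.0
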