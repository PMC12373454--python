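# Exp-1 marginal-effects scenario (four-condition design, 10-s preview,
# 37 subjects).  lambda_enc calibrated to a mean correlation of 0.273.
name: exp1_marginal
design: exp1
n_subjects: 37
n_blocks: 10
trials_per_block: 8
preview_s: 10.0
move_s: 5.0
piece_mean: 13.52
piece_sd: 5.97
piece_min: 4
piece_max: 31
seed: 0
target_corr: 0.273
geometry:
  screen_w: 1920
  screen_h: 1080
  square_px: 180.0
  origin_x: 150.0
  origin_y: 180.0
  smoothing_scale: 25.0
fixation:
  lambda_enc: 0.49
  lambda_subject_sd: 0.08
  lambda_diffuse: 0.12
  candidate_frac: 0.25
  center_sel_gain: 1.5
  center_alloc_gain: 2.5
  occupied_mass: 0.3
  jitter_px: 30.0
  dur_median_ms: 250.0
  dur_sigma: 0.4
  move_share: 0.55
  retrieval_window_s: 7.5
response:
  target_accuracy: 0.49
  b0: null
  b_prob: 0.233
  b_pred: 0.289
  b_inter: 0.0
  b_w: 0.0
  sigma_u: 0.5
  guess_q0: 0.0
  guess_q1: 1.0
confidence:
  intercept: 5.65
  b_prob: 0.09
  b_pred: 0.159
  b_w: 0.0
  sigma_u: 0.9
  sigma_e: 1.5
  floor: null
rt:
  intercept: 8.3
  b_prob: -0.2
  b_pred: -0.362
  b_w: 0.0
  sigma_u: 1.5
  sigma_e: 2.9
  floor: 0.5
retrieval:
  g_pred: -0.30060243908855894
  g_prob: -0.005010040651475983
  sigma_w: 0.9537363750569021
  pi_correct: 0.22
  pi_base: 0.42
  pi_slope: 0.22
  pi_min: 0.02
  pi_max: 0.78
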