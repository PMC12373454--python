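# Exp-2 null scenario: every planted effect is zero; used for type-I
# error and false-positive checks.
name: exp2_null
design: exp2
n_subjects: 95
n_blocks: 10
trials_per_block: 8
preview_s: 8.0
move_s: 5.0
piece_mean: 13.52
piece_sd: 5.97
piece_min: 4
piece_max: 31
seed: 0
target_corr: 0.354
geometry:
  screen_w: 1920
  screen_h: 1080
  square_px: 180.0
  origin_x: 150.0
  origin_y: 180.0
  smoothing_scale: 25.0
fixation:
  lambda_enc: 0.8421874999999999
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
  target_accuracy: 0.55
  b0: null
  b_prob: 0.0
  b_pred: 0.0
  b_inter: 0.0
  b_w: 0.0
  sigma_u: 0.5
  guess_q0: 0.0
  guess_q1: 1.0
confidence:
  intercept: 6.11
  b_prob: 0.0
  b_pred: 0.0
  b_w: 0.0
  sigma_u: 0.9
  sigma_e: 1.5
  floor: null
rt:
  intercept: 7.34
  b_prob: 0.0
  b_pred: 0.0
  b_w: 0.0
  sigma_u: 1.2
  sigma_e: 2.0
  floor: 0.5
retrieval:
  g_pred: 0.0
  g_prob: 0.0
  sigma_w: 1.0
  pi_correct: 0.22
  pi_base: 0.42
  pi_slope: 0.22
  pi_min: 0.02
  pi_max: 0.78
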