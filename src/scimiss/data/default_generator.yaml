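# Calibration defaults for the synthetic SCI cohort generator (version 1).
#
# Marginals target the complete-case cohort of a large acute-SCI clinical
# trial: ~79.3% male, ~74.4% cervical injuries, age mean ~32 years, AIS
# grade mix 65/11/20/4 (A/B/C/D), heavily zero-inflated LEMS (mean 2.7 at
# week 0, 11.9 at week 26, 12.6 at week 52; medians 0) and a recovery
# plateau between weeks 26 and 52.
#
# age_mean/age_sd parameterize the parent normal BEFORE truncation to
# [age_min, age_max]; (25.5, 14.8) yields a truncated mean of 32.0.
# Per-grade trajectory parameters were calibrated once against the
# published cohort moments (within +-30%); they are calibration defaults,
# not ground truth.
version: 1
n_patients: 546
p_male: 0.793
age_mean: 25.5
age_sd: 14.8
age_min: 16.0
age_max: 80.0
p_cervical: 0.744
grade_probs:
  A: 0.652
  B: 0.108
  C: 0.198
  D: 0.042
w16_fraction: 0.75
plateau_gain_mean: 1.5
plateau_gain_sd: 2.0
w26_missing_rate: 0.05
trajectories:
  # p_zero_w0: zero-inflation probability of week-0 LEMS
  # w0_mean / w0_shape: gamma for the non-zero week-0 scores
  # p_gain: probability of any motor recovery by week 26
  # gain_mean / gain_shape: gamma for the week-0 -> week-26 gain
  A: {p_zero_w0: 0.97, w0_mean: 5.0, w0_shape: 1.2, p_gain: 0.25, gain_mean: 12.0, gain_shape: 1.5}
  B: {p_zero_w0: 0.90, w0_mean: 6.0, w0_shape: 1.2, p_gain: 0.55, gain_mean: 20.0, gain_shape: 1.8}
  C: {p_zero_w0: 0.55, w0_mean: 10.0, w0_shape: 1.5, p_gain: 0.95, gain_mean: 30.0, gain_shape: 2.5}
  D: {p_zero_w0: 0.08, w0_mean: 28.0, w0_shape: 3.0, p_gain: 1.00, gain_mean: 18.0, gain_shape: 3.0}
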