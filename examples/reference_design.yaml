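# Paper-analog pipeline configuration: two sessions x 20 subjects (14
# shared), 4 ROIs x 100 voxels, 6x40 attention and 3x40 perception trials,
# latent sensory reactivation in V1/EVC only.
seed: 1
outdir: results/reference_design
sim:
  n_subjects_per_session: 20
  n_shared_subjects: 14
  n_voxels: 100
  rois: [V1, EVC, IPS, PFC]
  n_attention_runs: 6
  n_perception_runs: 3
  trials_per_attention_run: 40
  trials_per_perception_run: 40
  p_long_delay: 0.8
  tr_seconds: 2.0
effects:
  beta_sens: 1.0
  beta_att: 1.0
  lam_default: 0.6      # applied to V1 and EVC; IPS/PFC carry no latent template
  gamma_target: 1.0
  gamma_distractor: 0.3
  g: 0.3                # shared trial-gain coupling across ROIs
  b_rt: 0.3             # subject-level AMI -> RT slope (s)
  rt_trial_slope: 0.25  # trial-level reactivation -> RT slope (s)
analysis:
  shrinkage: 0.1
  window: [4.0, 6.0]
  n_perm: 200           # raise to 1000 for full-scale inference
  alpha: 0.05
  quantile: 0.25
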