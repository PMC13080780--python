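task:
  isi: 2.0
  stim_duration: 0.5
  task_duration: 240.0
  baseline_duration: 10.0
  gap_min: 7
  gap_max: 21
  seed: 0
  clock_offset: 0.0
  clock_jitter_sd: 0.0
cohort:
  n_participants: 53
  distribution:
    rt_shared_sd: 60.0
    rt_effect_sd: 25.0
    acc_target_sd: 0.03
    acc_standard_sd: 0.008
    p300_amp_target_sd: 0.6258
    p300_amp_standard_sd: 0.4929
    p300_latency_sd: 10.0
    hbo_amp_sd: 0.05
    hrf_peak_sd: 0.5
  eeg_rate: 250.0
  fnirs_rate: 10.0
profile:
  rt_mean_target: 718.0
  rt_mean_standard: 542.0
  rt_sd_target: 148.0
  rt_sd_standard: 122.0
  acc_target: 0.9458
  acc_standard: 0.9912
  p300_amp_target: 3.5397
  p300_amp_standard: 0.74667
  p300_latency: 356.0
  p300_fwhm: 200.0
  hbo_amp_target: 0.2
  hbo_amp_standard: 0.0
  hrf_peak_time: 9.0
  seed: 0
noise:
  eeg_background_sd: 5.0
  eeg_line_freq: 60.0
  eeg_line_amp: 2.0
  cardiac_freq: 1.2
  resp_freq: 0.25
  mayer_freq: 0.1
  systemic_amps:
    cardiac: 0.3
    resp: 0.08
    mayer: 0.1
    skin: 0.1
  skin_share: 0.7
  motion_spike_rate: 0.5
  motion_shift_rate: 0.2
  motion_spike_amp: 0.02
  motion_shift_amp: 0.01
  intensity_noise_od: 0.0001
  eeg_bad_impedance_fraction: 0.03
  sci_fail_fraction: 0.03
pipeline:
  impedance_max_kohm: 30.0
  sci_min: 0.4
  eeg_lowpass_hz: 45.0
  eeg_line_freq_hz: 60.0
  eeg_artifact_uv: 100.0
  eeg_epoch_window_s:
  - -0.2
  - 1.0
  p300_window_ms:
  - 250.0
  - 400.0
  fnirs_lowpass_hz: 0.08
  hbo_epoch_window_s:
  - -1.0
  - 20.0
  response_floor_ms: 100.0
  participant_exclusion_fraction: 0.5
  wilcoxon_continuity: false
  i0_mode: mean
seed: 1
output: pocketlab_out
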