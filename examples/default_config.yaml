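# Annotated default configuration for the lipstab simulator.
# Any subset of fields may be given; omitted fields keep their defaults.
# Load with `lipstab <cmd> --config this_file.yaml` or
# `lipstab.load_config(path)`.

grid:
  n: 40           # neurons per 1-D map; LIP maps are n x n
  v: 160.0        # visual field extent, deg ([-80, +80])
  dt: 1.0         # Euler step, ms
  tau_map: 10.0   # time constant of all sensory/LIP maps, ms

signals:
  rf_sigma0: 4.0    # foveal receptive-field width, deg
  rf_slope: 0.05    # RF width growth per deg of eccentricity
  fb_gain: 0.1      # attention-like LIP(PC) -> retina feedback gain
  fb_enabled: true  # the feedback is not critical for any result
  pc_sigma: 10.0    # proprioceptive eye-position bump width, deg
  pc_delay: 80.0    # registered eye position holds until offset + delay, ms
  pc_transition: 160.0  # linear update to the executed position, ms
  cd_sigma: 7.0         # corollary-discharge bump width, deg
  cd_sigma_rise: 30.0   # envelope rise width before saccade onset, ms
  cd_sigma_decay: 120.0 # slower envelope decay after onset, ms

lip:
  input_sigma: 6.0  # feedforward input kernel width, deg (row-normalised)
  diag_sigma: 15.0  # diagonal readout width, index units
  k_diag_pc: 0.035  # LIP(PC) -> head-centered readout gain
  k_diag_cd: 0.02   # LIP(CD) -> head-centered readout gain
  gain_pc: 2.7      # basis-function map drive gain
  gain_ff: 4.5      # anticipatory gain on the LIP(CD) visual drive
  k_fb: 0.65        # remapping feedback gain (the stabilising loop)
  fb_sat: 3.0       # saturation scale of the feedback transfer

decision:
  template_step: 0.5     # template lattice resolution, deg
  template_span: 14.0    # lattice half-width around the decision border, deg
  template_settle: 250.0 # fixation time used to build each template, ms
  match_gain: 0.6        # best fixation self-match after normalisation
  n_bins: 20             # Poisson sub-steps per ms
  s_max: 1.0             # spike amplitude
  tau_dn: 50.0           # accumulator time constant, ms
  baseline: 0.1          # accumulator starting value
  d_thresh: 0.6          # decision threshold (0.3-0.9 all behave alike here)
  timeout: 100.0         # ms; larger accumulator wins at timeout
  start_post_offset: 28.0  # accumulation onset after saccade offset, ms
  start_post_stim: 60.0    # accumulation onset after late reappearance, ms

oculomotor:
  undershoot_mean: 0.52  # mean saccadic endpoint undershoot, deg
  scatter_sd: 0.58       # endpoint scatter SD, deg
  duration_base: 23.0    # main-sequence intercept, ms
  duration_slope: 2.7    # main-sequence slope, ms/deg

remap:
  amplitude: 14.0      # saccade amplitude, deg
  rf_position: -14.0   # probe in the present receptive field, deg
  frf_position: 0.0    # probe in the future receptive field, deg
  flash_duration: 100.0
  flash_from: -500.0   # earliest flash, ms relative to saccade onset
  flash_to: 100.0
  flash_step: 25.0
  window: [50.0, 350.0]  # response window after flash onset, ms
  onset_fraction: 0.1    # response-onset criterion (fraction of curve max)
  saccade_onset: 700.0   # ms from trial start

ssd:
  amplitude: 8.0
  displacement_min: -4.0
  displacement_max: 4.0
  displacement_step: 0.5
  displacement_delay: 30.0  # displacement after saccade onset, ms
  blank_gap: 250.0          # blank before displaced reappearance, ms
  pre_duration: 500.0       # target visible before saccade onset, ms
  saccade_onset: 600.0
  n_trials: 20              # trials per displacement
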