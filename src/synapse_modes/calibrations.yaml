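# Packaged default calibrations for the zebrafish CaP NMJ simulator.
#
# Units: seconds, µm, µm/s, µM, pA, ms as suffixed. The bouton calcium model
# has two components above a 0.1 µM resting level: a fast AP-driven component
# (scaled by pq_scale, i.e. P/Q channel function) and a slow "bulk" component
# that arrives as a propagating front and drives asynchronous release.
# EGTA-dependent entries: higher EGTA slows the front (wave_speed), delays its
# initiation (wave_onset), and slows local accumulation (tau_bulk/tau_fast/lag).

quantal:
  mean_amp_pA: 637.0
  cv: 0.25
  rise_tau_ms: 0.3
  decay_tau_ms: 1.0
  noise_sd_pA: 5.0
  sample_rate_hz: 20000.0

release:
  sync_p0: 0.85                # initial per-spike release probability
  sync_depress_tau_s: 2.0      # exponential depression of sync probability
  sync_latency_mean_ms: 0.5
  sync_latency_sd_ms: 0.5
  sync_latency_clip_ms: [0.1, 2.0]
  async_rate_max_hz: 170.0     # cell async rate at full drive, undepleted
  deplete_k: 0.25              # pool depletion per unit integrated drive
  spont_rate_hz: 0.25
  hill_k: 0.5                  # half-activation of the release sensor (bulk fraction)
  hill_h: 5.0                  # Hill coefficient of the calcium sensor

calcium:
  rest_uM: 0.1
  fast_amp_uM: 0.45            # AP-driven component amplitude (x pq_scale)
  bulk_amp_uM: 0.45            # propagating component amplitude
  tau_off_s: 8.0               # decay after stimulus end
  relax_frac: 0.05             # mild late relaxation of bouton signal
  relax_tau_s: 5.0

imaging:
  frame_dt_s: 0.033
  f_rest_au: 50.0
  f_max_au: 200.0
  shot_eta: 0.3                # green noise SD = eta * sqrt(F)
  red_mean_au: 100.0
  red_sd_au: 2.0

indicators:
  fluo4:
    kd_uM: 0.345
  fluo5f:
    kd_uM: 2.3

egta:
  "0.5":
    wave_speed_um_per_s: 74.0
    wave_onset_s: 0.53
    tau_bulk_s: 3.0
    tau_fast_s: 0.6
    lag_s: 0.05
    onset_jitter_scale_s: 0.10
    rate_scale: 1.0
  "5":
    wave_speed_um_per_s: 35.0
    wave_onset_s: 3.60
    tau_bulk_s: 3.0
    tau_fast_s: 1.4
    lag_s: 0.45
    onset_jitter_scale_s: 0.25
    rate_scale: 1.0
  "25":
    # qualitative regime: a single surviving recording motivates these
    wave_speed_um_per_s: 20.0
    wave_onset_s: 8.0
    tau_bulk_s: 4.0
    tau_fast_s: 2.5
    lag_s: 1.0
    onset_jitter_scale_s: 0.5
    rate_scale: 0.02

conditions:
  control:
    pq_scale: 1.0
  gvia:
    pq_scale: 0.0
  tb204a:
    pq_scale: 0.3
  ttx:
    pq_scale: 0.0

# Single-cell fixture: an example neuron whose bouton onset-vs-distance
# relation fits a 57 um/s line (slower than the pooled 74 um/s average).
fixtures:
  slow_wave_cell:
    condition: gvia
    egta_mM: 0.5
    indicator: fluo5f
    wave_speed_um_per_s: 57.0
    seed: 1207

ttx:
  v_slow_um_per_s: 3.0
  frame_dt_s: 1.0
  duration_s: 95.0
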