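# Default run configuration. Every numeric default of the pipeline lives
# here; presets expand to the three experimental designs.
sample_rate_hz: 1000.0
audio_sample_rate_hz: 44100
carrier_hz: 500.0
soa_grid_ms: [-500, -400, -300, -200, -100, 0, 100, 200, 300, 400, 500]
max_soa_ms: 500.0
n_reps: 5
fft_band_hz: [0.5, 10.0]
speech_target_hz: 3.0
speech_tol_hz: 0.5
speech_jitter_cv: 0.2
speech_amp_cv: 0.3
n_speech_tokens: 5
gauss_r2_threshold: 0.5
logistic_r2_threshold: 0.3
priors:
  a_range: [0.85, 1.0]
  b_mean: 50.0
  b_sd: 40.0
  c_range: [200.0, 500.0]
  unsure_range: [0.0, 0.15]
  confident_range: [0.55, 0.9]
presets:
  exp1:
    conditions:
      - {label: rhythmic-1Hz, mode: rhythmic, freq_hz: 1, stream_mode: fixed_duration, stream_value: 3}
      - {label: rhythmic-2Hz, mode: rhythmic, freq_hz: 2, stream_mode: fixed_duration, stream_value: 3}
      - {label: rhythmic-3Hz, mode: rhythmic, freq_hz: 3, stream_mode: fixed_duration, stream_value: 3}
  exp2:
    conditions:
      - {label: rhythmic-1Hz-3p, mode: rhythmic, freq_hz: 1, stream_mode: fixed_pulses, stream_value: 3}
      - {label: rhythmic-2Hz-3p, mode: rhythmic, freq_hz: 2, stream_mode: fixed_pulses, stream_value: 3}
      - {label: rhythmic-3Hz-3p, mode: rhythmic, freq_hz: 3, stream_mode: fixed_pulses, stream_value: 3}
  exp3:
    conditions:
      - {label: rhythmic-3Hz, mode: rhythmic, freq_hz: 3, stream_mode: fixed_duration, stream_value: 3}
      - {label: speech-like, mode: speech-like, freq_hz: 3, stream_mode: fixed_duration, stream_value: 3}
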