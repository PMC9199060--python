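# Canonical fusbeam run configuration. All quantities SI; units are spelled
# out in the key names. Unknown keys are rejected.
geometry:
  n_elements: 128
  pitch_m: 3.0e-4
  f0_hz: 5.0e+6
  fs_hz: 2.0e+7
  c_m_per_s: 1540.0
pulses:
  therapy_cycles: 160
  visualization_cycles: 2
image:
  z_min_m: 2.4e-2
  z_max_m: 3.6e-2
  x_min_m: -6.0e-3
  x_max_m: 6.0e-3
therapy:
  treat_window_s: 0.050
  prf_hz: 3000.0
  image_window_s: 2.0
  n_pwc_angles: 11
  pwc_span_deg: 18.0
  frames_per_image_window: 1
transmits:
  focus_points_m: [[0.0, 3.0e-2]]
  plane_angles_deg: [-18.0, 0.0, 18.0]
seed: 0
noise_sd: 0.0
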