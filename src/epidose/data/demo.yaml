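# Demo configuration: the sinusoid amplitude/frequency grid plus two
# irregular patient-like breathing traces, analysed against the static
# reference at the four standard gamma criteria.
phantom:
  separation_max: 16.0
beam:
  field_size_x: 14.0
  field_size_y: 8.0
  wedge_min: 0.5
  calib_field_size: 26.0
acquisition:
  n_frames: 60
  frame_time: 0.43
  pixels: 256
  pixel_pitch: 0.1
  noise_scale: 0.005
motion_set:
  amplitudes: [0.5, 1.0, 1.5]
  frequencies: [12.0, 15.0, 20.0]
  n_patient_traces: 2
  trace_duration: 60.0
analysis:
  gamma_criteria: [[5, 5], [3, 3], [2, 2], [1, 1]]
  diff_thresholds: [5.0, 3.0, 2.0, 1.0]
  gamma_interp_factor: 10
seed: 0
out: epidose_run
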