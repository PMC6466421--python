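# A quick 20-pair scan on the 4x-downscaled grid (same physical field of view).
acquisition:
  n_frame_pairs: 20
  pixels_x: 320
  pixels_y: 240
population:
  cd3_concentration: 800.0   # cells/µL; half CD4+ -> 400 CD4/µL
  cd4_fraction: 0.5
noise:
  background_level: 20.0
  vignette_strength: 0.3
  shot_noise: true
  read_noise_sd: 2.0
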