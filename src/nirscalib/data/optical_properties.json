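{
  "wavelength_nm": 735,
  "layers": {
    "void": {"mu_a": 0.0, "mu_s": 0.0, "g": 0.0, "n": 1.0},
    "scalp_muscle": {"mu_a": 0.016, "mu_s": 19.0, "g": 0.9, "n": 1.6},
    "cranium": {"mu_a": 0.018, "mu_s": 16.0, "g": 0.9, "n": 1.56},
    "csf": {"mu_a": 0.004, "mu_s": 0.3, "g": 0.0, "n": 1.33},
    "brain": {"mu_a": 0.09, "mu_s": 21.5, "g": 0.9, "n": 1.4}
  }
}
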