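{
  "e0": 600.0,
  "f_M": 1.76,
  "tau": 4.5,
  "u_plus": 0.2,
  "u_minus": 0.2,
  "sigma_max": 8.54,
  "sigma_rest": 2.562,
  "sigma_final": 6.832,
  "phi_ramp": 0.9,
  "phi_final": 0.2
}
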