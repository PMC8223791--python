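{
  "_comment": "Dipolar prefactors K = (mu0/4pi) * gamma_i * gamma_j * hbar / (2*pi), in Hz*A^3. D_max(r) = K / r^3.",
  "HH": 120120.0,
  "CH": 30210.0,
  "NH": -12170.0,
  "CC": 7598.0,
  "CN": -3062.0
}
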