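{
  "mu_max": 0.22082992175037053,
  "K": 112.9018121911038,
  "par_compensation": 0.2
}
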