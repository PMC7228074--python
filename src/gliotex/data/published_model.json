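{
  "variables": [
    "T2_NCRNET_F_szm.z.perc",
    "T2_NCRNET_F_szm.zs.var",
    "T1Gd_NCRNET_F_szm.zsnu"
  ],
  "coefficients": [13.693, -0.41, 31.842],
  "intercept": -19.5,
  "w": 1,
  "combination": "T1Gd:NCRNET+T2:NCRNET",
  "targets": [-10.0, 10.0]
}
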