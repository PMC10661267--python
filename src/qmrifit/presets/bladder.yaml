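name: bladder
dce_bounds:
  ktrans: [0.0, 3.0]
  ve: [0.001, 1.0]
  vp: [0.0, 0.4]
  fp: [0.0, 400.0]
  ps: [0.0, 3.0]
  tau_i: [0.05, 3.0]
dw_bounds:
  d: [1.0e-6, 3.0e-3]
  dstar: [3.0e-3, 0.3]
  f: [0.0, 0.5]
  kapp: [0.0, 3.0]
  k: [0.0, 3.0]
ivim_b_threshold: 200
t10_blood: 1.66
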