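# Brain (metastasis / glioma) preset: literature-informed defaults, editable.
name: brain
dce_bounds:
  ktrans: [0.0, 2.0]      # min^-1
  ve: [0.001, 1.0]
  vp: [0.0, 0.3]
  fp: [0.0, 300.0]        # mL/min/100mL
  ps: [0.0, 2.0]          # min^-1
  tau_i: [0.05, 3.0]      # s
dw_bounds:
  d: [1.0e-6, 3.5e-3]     # mm^2/s
  dstar: [3.0e-3, 0.3]
  f: [0.0, 0.5]
  kapp: [0.0, 3.0]
  k: [0.0, 3.0]
ivim_b_threshold: 200     # s/mm^2
t10_blood: 1.66           # s at 3T
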