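# Published coefficient estimates and piece domains of the main-stem leaf
# biomass partitioning model for rapeseed (Brassica napus L.).
#
# Coefficients are stored to the three printed decimals; no extra
# precision is re-derived.  Interval strings use standard open/closed
# bracket notation over normalized leaf rank (nLR).  Interior breakpoints
# belong to the upper piece; the last piece of each stage is closed at
# its upper end.
nlr_model:
  form: logarithmic
  domain: "(0, 1]"
  coefficients:
    Llr1: 0.618
    Llr2: 0.900
stages:
  early_seedling:
    - form: linear
      domain: "(0.10, 0.24)"
      coefficients: {Les1: 1.836, Les2: -0.162}
    - form: linear
      domain: "[0.24, 0.38]"
      coefficients: {Les3: -1.256, Les4: 0.506}
  mid_seedling:
    - form: linear
      domain: "(0.10, 0.25)"
      coefficients: {Lms1: 1.480, Lms2: -0.131}
    - form: quadratic
      domain: "[0.25, 0.50]"
      coefficients: {Lms3: 3.426, Lms4: -3.314, Lms5: 0.826}
  late_seedling:
    - form: linear
      domain: "(0.10, 0.27)"
      coefficients: {Lls1: 1.060, Lls2: -0.100}
    - form: power
      domain: "[0.27, 0.63]"
      coefficients: {Lls3: 1.562, Lls4: -7.998}
  budding:
    - form: power
      domain: "(0.17, 0.45)"
      coefficients: {Lbu1: 0.262, Lbu2: 1.000}
    - form: quadratic
      domain: "[0.45, 0.93]"
      coefficients: {Lbu3: 0.511, Lbu4: -0.916, Lbu5: 0.413}
  bolting:
    - form: quadratic
      domain: "(0.21, 0.50)"
      coefficients: {Lbo1: -0.012, Lbo2: 0.290, Lbo3: -0.034}
    - form: quadratic
      domain: "[0.50, 1.0]"
      coefficients: {Lbo4: 0.605, Lbo5: -1.130, Lbo6: 0.531}
  early_blooming:
    - form: power
      domain: "(0.21, 0.55)"
      coefficients: {Leb1: 0.498, Leb2: 2.213}
    - form: quadratic
      domain: "[0.55, 1.0]"
      coefficients: {Leb3: 0.971, Leb4: -1.792, Leb5: 0.827}
  full_blooming:
    - form: linear
      domain: "(0.42, 0.60)"
      coefficients: {Lfb1: 0.342, Lfb2: -0.067}
    - form: quadratic
      domain: "[0.60, 1.0]"
      coefficients: {Lfb3: 0.870, Lfb4: -1.713, Lfb5: 0.848}
  late_blooming:
    - form: quadratic
      domain: "[0.50, 1.0]"
      coefficients: {Llb1: 0.053, Llb2: -0.486, Llb3: 0.423}
  mature:
    - form: logarithmic
      domain: "(0.71, 1.0]"
      coefficients: {Lm1: -0.814, Lm2: 0.024}
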