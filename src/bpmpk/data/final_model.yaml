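# Final biapenem population-PK model for adult sepsis patients.
# Two-compartment, first-order elimination; linear creatinine-clearance
# effect on CL and linear blood-urea-nitrogen effect on Q; exponential IIV
# on CL and Q (variances), additive residual error (variance, mg^2/L^2).
n_compartments: 2
theta:
  cl: 8.33     # L/h at CLCr 78.2 mL/min
  v1: 13.4     # L
  q: 3.75      # L/h at BUN 6.8 mmol/L
  v2: 60.4     # L
effects:
  - {parameter: cl, covariate: clcr, form: linear, ref: 78.2, coef: 0.0046}
  - {parameter: q, covariate: bun, form: linear, ref: 6.8, coef: 0.112}
omega:
  cl: 0.0591
  q: 1.12
sigma:
  kind: additive
  add: 0.591
  prop: 0.0
variance_scale: variance
fu: 1.0
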