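# Core path model 4a: focal exposure D5D, outcome SBP z-score.
# Covariate blocks (sex, age, country indicators, parental education,
# lifestyle and lipid covariates) are configurable additions; residual
# covariances default to zero and the exogenous block is free unless a
# pair is listed under fixed_zero.
variables: [SNP, D5D, BMI, SBP]
edges:
  - [SNP, D5D]
  - [SNP, BMI]
  - [D5D, BMI]
  - [SNP, SBP]
  - [D5D, SBP]
  - [BMI, SBP]
covariances: []
fixed_zero: []
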