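# Core path model 1a: focal exposure DGLA, outcome SBP z-score.
# Covariate blocks (sex, age, country indicators, parental education,
# lifestyle and lipid covariates) are configurable additions; residual
# covariances default to zero and the exogenous block is free unless a
# pair is listed under fixed_zero.
variables: [SNP, DGLA, BMI, SBP]
edges:
  - [SNP, DGLA]
  - [SNP, BMI]
  - [DGLA, BMI]
  - [SNP, SBP]
  - [DGLA, SBP]
  - [BMI, SBP]
covariances: []
fixed_zero: []
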