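# Core path model 3b: focal exposure EPA, outcome DBP z-score.
# Covariate blocks (sex, age, country indicators, parental education,
# lifestyle and lipid covariates) are configurable additions; residual
# covariances default to zero and the exogenous block is free unless a
# pair is listed under fixed_zero.
variables: [SNP, EPA, BMI, DBP]
edges:
  - [SNP, EPA]
  - [SNP, BMI]
  - [EPA, BMI]
  - [SNP, DBP]
  - [EPA, DBP]
  - [BMI, DBP]
covariances: []
fixed_zero: []
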