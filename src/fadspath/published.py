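"""Published standardized path coefficients used as analysis inputs.

The child-cohort study this package re-analyses did not deposit raw data,
but its result tables print the standardized direct effects for eight path
models (four fatty-acid exposures x two blood-pressure outcomes) plus a
weight-status-stratified EPA analysis and the rs174546 genotype counts.
Those printed numbers are the inputs for two uses:

* worked examples / identity checks — every printed indirect effect must
  equal the sum of products of the printed direct effects along the
  mediating paths;
* generating values for the synthetic cohorts on which the ML engine's
  parameter recovery is demonstrated.

Variable naming: ``SNP`` is the additive rs174546 T-allele count, ``FA``
the model's focal fatty-acid exposure (DGLA, ARA, EPA or the D5D index),
``BMI`` the BMI z-score, ``SBP``/``DBP`` the blood-pressure z-scores.
"""

from __future__ import annotations

#: Standardized direct effects per model.  Keys are edge (source, target);
#: "FA" is the focal exposure named in EXPOSURE.
MODEL_DIRECT_EFFECTS: dict[str, dict[tuple[str, str], float]] = {
    # --- systolic models ---
    "1a": {
        ("SNP", "FA"): 0.353,
        ("FA", "BMI"): 0.164,
        ("SNP", "BMI"): -0.134,
        ("BMI", "SBP"): 0.288,
        ("FA", "SBP"): -0.002,
        ("SNP", "SBP"): 0.043,
    },
    "2a": {
        ("SNP", "FA"): -0.237,
        ("FA", "BMI"): 0.076,
        ("SNP", "BMI"): -0.058,
        ("BMI", "SBP"): 0.282,
        ("FA", "SBP"): 0.149,
        ("SNP", "SBP"): 0.077,
    },
    "3a": {
        ("SNP", "FA"): -0.092,
        ("FA", "BMI"): 0.147,
        ("SNP", "BMI"): -0.061,
        ("BMI", "SBP"): 0.284,
        ("FA", "SBP"): 0.027,
        ("SNP", "SBP"): 0.044,
    },
    "4a": {
        ("SNP", "FA"): -0.527,
        ("FA", "BMI"): -0.097,
        ("SNP", "BMI"): -0.125,
        ("BMI", "SBP"): 0.291,
        ("FA", "SBP"): 0.035,
        ("SNP", "SBP"): 0.061,
    },
    # --- diastolic models: upstream (FA/BMI) rows repeat the systolic panel ---
    "1b": {
        ("SNP", "FA"): 0.353,
        ("FA", "BMI"): 0.164,
        ("SNP", "BMI"): -0.134,
        ("BMI", "DBP"): 0.139,
        ("FA", "DBP"): -0.003,
        ("SNP", "DBP"): -0.006,
    },
    "2b": {
        ("SNP", "FA"): -0.237,
        ("FA", "BMI"): 0.076,
        ("SNP", "BMI"): -0.058,
        ("BMI", "DBP"): 0.134,
        ("FA", "DBP"): 0.103,
        ("SNP", "DBP"): 0.017,
    },
    "3b": {
        ("SNP", "FA"): -0.092,
        ("FA", "BMI"): 0.147,
        ("SNP", "BMI"): -0.061,
        ("BMI", "DBP"): 0.134,
        ("FA", "DBP"): 0.031,
        ("SNP", "DBP"): -0.004,
    },
    "4b": {
        ("SNP", "FA"): -0.527,
        ("FA", "BMI"): -0.097,
        ("BMI", "DBP"): 0.141,
        ("SNP", "BMI"): -0.125,
        ("FA", "DBP"): 0.036,
        ("SNP", "DBP"): 0.012,
    },
}

#: Focal exposure and outcome per model id.
EXPOSURE: dict[str, str] = {
    "1a": "DGLA", "2a": "ARA", "3a": "EPA", "4a": "D5D",
    "1b": "DGLA", "2b": "ARA", "3b": "EPA", "4b": "D5D",
}
OUTCOME: dict[str, str] = {m: ("SBP" if m.endswith("a") else "DBP")
                           for m in MODEL_DIRECT_EFFECTS}

#: Printed indirect-effect cells (total over all mediating paths for the
#: SNP→BP rows), for the identity checks.
PUBLISHED_INDIRECT: dict[str, dict[tuple[str, str], float]] = {
    "1a": {("SNP", "BMI"): 0.058, ("SNP", "SBP"): -0.023, ("FA", "SBP"): 0.047},
    "2a": {("SNP", "BMI"): -0.018, ("SNP", "SBP"): -0.057, ("FA", "SBP"): 0.021},
    "3a": {("SNP", "BMI"): -0.014, ("SNP", "SBP"): -0.024, ("FA", "SBP"): 0.042},
    "4a": {("SNP", "BMI"): 0.051, ("SNP", "SBP"): -0.040, ("FA", "SBP"): -0.028},
    "1b": {("SNP", "BMI"): 0.058, ("SNP", "DBP"): -0.012, ("FA", "DBP"): 0.023},
    "2b": {("SNP", "BMI"): -0.018, ("SNP", "DBP"): -0.035, ("FA", "DBP"): 0.010},
    "3b": {("SNP", "BMI"): -0.014, ("SNP", "DBP"): -0.013, ("FA", "DBP"): 0.020},
    "4b": {("SNP", "BMI"): 0.051, ("SNP", "DBP"): -0.029, ("FA", "DBP"): -0.014},
}

#: Reported total effect of the SNP on SBP in the ARA model (direct 0.077
#: plus the mediated paths).
TOTAL_EFFECT_SNP_SBP_ARA: float = 0.020

#: rs174546 genotype counts (CC, CT, TT) in the 520-child analysis sample.
GENOTYPE_COUNTS: tuple[int, int, int] = (266, 206, 48)

#: Reported minor-allele frequency (percent) and HWE p-value.
REPORTED_MAF_PERCENT: float = 29.0
REPORTED_HWE_P: float = 0.395

#: Weight-status-stratified EPA analysis: standardized direct effects per
#: stratum.  BMI→BP coefficients are not printed in the stratified table;
#: the values used for synthetic generation are implied by the printed
#: indirect/direct ratios (see docs/methods.md).
STRATIFIED_EPA: dict[str, dict[tuple[str, str], float]] = {
    "thin_normal": {
        ("EPA", "BMI"): -0.206,
        ("EPA", "SBP"): -0.042,
        ("BMI", "SBP"): 0.140,
    },
    "overweight_obese": {
        ("EPA", "BMI"): 0.535,
        ("EPA", "SBP"): 0.155,
        ("BMI", "SBP"): 0.140,
    },
}

#: Stratum sizes in the published analysis (thin/normal, overweight/obese).
STRATUM_SIZES: tuple[int, int] = (316, 204)

#: Analysis-sample marginals, mean and SD on the raw scale, for rescaling
#: synthetic cohorts ("% wt/wt" for fatty acids, z-scores for BMI/BP).
MARGINALS: dict[str, tuple[float, float]] = {
    "DGLA": (1.22, 0.25),
    "ARA": (7.53, 1.34),
    "EPA": (0.27, 0.11),
    "D5D": (6.32, 1.29),
    "BMI": (0.88, 1.27),
    "SBP": (0.41, 0.78),
    "DBP": (0.63, 0.59),
}

#: Study sample size and minor-allele frequency.
N_SUBJECTS: int = 520
MAF: float = 0.29
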