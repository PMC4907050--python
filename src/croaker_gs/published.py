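"""Reported summary values from the large yellow croaker genomic-selection study.

These printed cohort-level numbers are inputs to the desk-scale analyses
(accuracy-curve fitting and extrapolation) and to the synthetic presets;
the underlying raw genotype/phenotype data were never released, so
individual-level results are emulated rather than reproduced.
"""

# Full-cohort REML heritability estimates per trait.
HERITABILITY = {"bw": 0.604, "bl": 0.586, "hufa": 0.438}

# Mean predictive abilities (20-replicate cross-validation) by training size.
TRAINING_SIZES = (100, 200, 300, 400)
MEAN_ABILITIES = {
    ("bw", "gblup"): (0.315, 0.350, 0.384, 0.406),
    ("bw", "embayesb"): (0.293, 0.350, 0.359, 0.371),
    ("bl", "gblup"): (0.284, 0.342, 0.375, 0.404),
    ("bl", "embayesb"): (0.268, 0.314, 0.356, 0.374),
}

# Per-trait GWAS significance thresholds used for marker pre-selection.
GWAS_THRESHOLDS = {"bw": 1e-5, "bl": 1e-6, "hufa": 1e-4}

# Target predictive accuracy for the required-training-size extrapolation.
TARGET_ACCURACY = 0.8
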