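"""Published DEAP benchmark values for the TQWT + BGWO emotion pipeline.

These are the reported per-subject optimal accuracies, per-sub-band
per-feature accuracies, and cross-method kappa comparisons for the
32-subject DEAP cohort.  They serve as inputs to the arithmetic
consistency checks: the package's kappa normalization and table
aggregation must reproduce the reported summary numbers from these cells.
"""

# Per-subject optimal-parameter accuracies (%), before and after BGWO
# selection, 32 subjects.  Reported column means: 65.20 / 68.24; reported
# maximum after selection: 90.48.
SUBJECT_ACC_BEFORE = [
    52.38, 42.86, 89.68, 52.78, 59.52, 82.14, 59.52, 67.86,
    77.38, 79.76, 57.94, 57.54, 52.38, 57.54, 85.71, 85.32,
    82.94, 70.24, 68.25, 88.10, 62.70, 51.59, 67.86, 70.24,
    54.37, 51.98, 55.16, 42.46, 45.63, 67.06, 73.02, 74.60,
]
SUBJECT_ACC_AFTER = [
    60.32, 46.03, 90.48, 54.76, 59.92, 83.33, 63.10, 74.21,
    77.78, 80.56, 58.33, 58.73, 55.95, 59.92, 87.30, 85.71,
    83.33, 73.41, 69.84, 88.10, 72.22, 55.16, 72.22, 75.40,
    61.90, 60.32, 57.14, 43.25, 48.41, 75.40, 73.41, 77.78,
]

# Per-(feature, sub-band) accuracies (%) on the fused 32-subject cohort,
# before and after BGWO; columns are sub-bands 1..5.  Reported mean
# per-sub-band accuracy increase: 4.97.
SUBBAND_ACC_BEFORE = {
    "2dif":   [57.81, 58.20, 58.59, 57.81, 59.38],
    "2ndif":  [58.98, 58.59, 60.16, 57.42, 56.64],
    "HC":     [55.86, 61.33, 58.59, 59.37, 58.59],
    "HM":     [55.86, 55.47, 56.64, 57.03, 56.25],
    "SampEn": [57.42, 58.21, 57.42, 59.77, 57.03],
}
SUBBAND_ACC_AFTER = {
    "2dif":   [63.67, 63.28, 61.72, 61.36, 62.11],
    "2ndif":  [67.58, 64.45, 66.41, 63.28, 62.11],
    "HC":     [60.94, 63.67, 61.33, 63.67, 65.62],
    "HM":     [61.33, 61.72, 62.25, 62.25, 63.28],
    "SampEn": [63.28, 61.33, 62.11, 63.28, 60.55],
}

# Overall fused-cohort results per feature type: (All Acc %, Sen %, Spe %,
# kappa).  Reported All-Acc mean 62.34 with kappa 0.53.
ALL_FUSED = {
    "2dif":   (62.1, 70.25, 81.33, 0.5263),
    "2ndif":  (62.5, 64.19, 82.01, 0.5313),
    "HC":     (62.6, 62.12, 79.29, 0.5325),
    "HM":     (62.4, 65.13, 68.70, 0.5300),
    "SampEn": (62.1, 64.40, 79.30, 0.5263),
}

# Cross-method comparison: (accuracy %, n_classes, reported kappa).
# Accuracies of problems with different class counts are normalized onto
# one scale by the uniform-chance kappa.
METHOD_KAPPAS = [
    (62.00, 2, 0.24), (57.60, 2, 0.15), (55.40, 2, 0.11),   # corr. coeff + NB
    (65.00, 2, 0.30), (68.00, 2, 0.36),                      # LRFS + LSSVM/NB
    (69.00, 3, 0.54), (67.00, 3, 0.51), (65.00, 3, 0.48), (65.00, 3, 0.48),
    (63.31, 3, 0.45),                                        # MACI
    (58.75, 4, 0.45),                                        # ReliefF + SVM
    (59.06, 4, 0.45),                                        # FAWT + SVM
    (73.14, 2, 0.46), (73.06, 2, 0.46),                      # mRMR + SVM
    (62.33, 3, 0.43), (60.70, 3, 0.41),
    (46.69, 5, 0.33), (45.32, 5, 0.32),
    (68.24, 5, 0.603),                                       # this pipeline
]

# Headline kappas: mean / max of the after-selection subject accuracies,
# and the fused-cohort mean accuracy.
HEADLINE_KAPPAS = [(68.24, 5, 0.603), (90.48, 5, 0.88), (62.34, 5, 0.53)]
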