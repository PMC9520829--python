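"""Published summary statistics from a large provincial COPD claims cohort.

These printed table cells from a population-based Ontario study of
newly diagnosed COPD patients (n = 450,837) serve as arithmetic
cross-checks: the package's standardized-difference and proportion
formulas, applied to the printed counts and moments, must reproduce the
printed derived values. They are inputs for verification, never fitted
or tuned quantities.
"""

# Cohort and group sizes
N_COHORT = 450_837
N_FP_PREDOMINANT = 425_070
N_SP_PREDOMINANT = 25_767
N_LOW_COCI = 227_082
N_HIGH_COCI = 223_755

# Outpatient-visit distribution (all patients)
N_VISITS_OVER_20 = 319_879

# 30-day readmissions within the FP-predominant group
N_READMISSION_30D_FP = 35_600

# Zero-admission counts by continuity category
N_ZERO_ADMISSIONS_LOW = 106_548
N_ZERO_ADMISSIONS_HIGH = 139_766

# Mean +/- SD of per-patient admission counts, printed alongside the
# standardized differences they imply (2 decimal places).
MEAN_ADMISSIONS_LOW = (1.42, 2.27)
MEAN_ADMISSIONS_HIGH = (0.72, 1.32)
PRINTED_D_ADMISSIONS_COCI = 0.38

MEAN_ADMISSIONS_FP = (1.03, 1.83)
MEAN_ADMISSIONS_SP = (1.77, 2.61)
PRINTED_D_ADMISSIONS_PROVIDER = 0.33

MEAN_COPD_ADMISSIONS_FP = (0.19, 0.74)
MEAN_COPD_ADMISSIONS_SP = (0.47, 1.31)
PRINTED_D_COPD_ADMISSIONS_PROVIDER = 0.26

# Printed percentages the count cells imply (1 decimal place)
PRINTED_PCT_LOW_COCI = 50.4
PRINTED_PCT_HIGH_COCI = 49.6
PRINTED_PCT_VISITS_OVER_20 = 71.0
PRINTED_PCT_READMISSION_30D_FP = 8.4
PRINTED_PCT_ZERO_ADMISSIONS_LOW = 46.9
PRINTED_PCT_ZERO_ADMISSIONS_HIGH = 62.5

# Overall continuity summaries (for orientation, not assertion targets)
MEAN_COC_ALL = (0.51, 0.26)
MEAN_UPC_ALL = (0.59, 0.22)
MEAN_SECON_ALL = (0.64, 0.23)
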