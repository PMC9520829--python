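"""Fit the 12-model association suite: 4 outcomes x 3 adjustment tiers.

The exposure is the low-continuity category (high as reference); Model
A adjusts for age, sex, comorbidity, socioeconomic status and rurality;
Model B adds the predominant provider group. The generator plants a
low-continuity odds ratio of 2.25 on the admission outcome.
"""

from concare import SimulationConfig, generate_dataset, run_pipeline

res = run_pipeline(generate_dataset(SimulationConfig(n_patients=20000, seed=42)))
suite = res.suite.copy()
for col in ("odds_ratio", "ci_low", "ci_high"):
    suite[col] = suite[col].round(2)
print(suite.to_string(index=False))
print(
    "\nEach row is the odds of the outcome for low- vs high-continuity "
    "patients;\nvalues above 1 mean low continuity is associated with more "
    "unplanned care.\nThe adjusted any-admission OR should sit near the "
    "planted value of 2.25."
)
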