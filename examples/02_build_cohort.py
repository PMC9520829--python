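"""Derive the incident COPD cohort from the linked tables.

Applies the claims case definition over the 2005–2013 recruitment
window, the eligibility exclusions, and five-year censored follow-up.
"""

from concare import SimulationConfig, build_cohort, generate_dataset

tables = generate_dataset(SimulationConfig(n_patients=1000, seed=42))
cohort = build_cohort(tables)

eligible = cohort[cohort["eligible"]]
print(f"candidates with a qualifying event: {len(cohort)}")
print(f"eligible cohort members:            {len(eligible)}")
print("\nexclusions (first matching reason):")
print(cohort.loc[~cohort["eligible"], "exclusion_reason"].value_counts().to_string())
print("\ncensoring of follow-up:")
print(eligible["censor_reason"].value_counts().to_string())
print(f"\nmedian age at index: {eligible['age_at_index'].median():.1f} years")
# end_of_window = completed the full five years; death and moved
# (loss of provincial coverage) truncate follow-up early.
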