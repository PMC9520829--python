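"""Derive unplanned-utilization outcomes over follow-up.

Counts admissions (all-cause and COPD-related), 30-day readmissions,
ED visit classes and in-hospital death for every cohort member.
"""

from concare import (
    SimulationConfig,
    bin_series,
    build_cohort,
    generate_dataset,
    summarize_utilization,
)

tables = generate_dataset(SimulationConfig(n_patients=1000, seed=42))
cohort = build_cohort(tables)
outcomes = summarize_utilization(tables["discharges"], tables["ed_visits"], cohort)

print(f"patients summarized: {len(outcomes)}")
print(f"any admission:        {100 * outcomes['any_admission'].mean():.1f}%")
print(f"any 30-day readmit:   {100 * outcomes['any_readmission_30d'].mean():.1f}%")
print(f"any ED visit:         {100 * (outcomes['n_ed_all'] >= 1).mean():.1f}%")
print(f"in-hospital death:    {100 * outcomes['died_in_hospital'].mean():.1f}%")
print("\nadmission-count bins (all cause):")
print(bin_series(outcomes["n_admissions_all"]).value_counts().sort_index().to_string())
# The four bins partition the cohort exactly — the same conservation law
# the reporting tables rely on.
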