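"""Generate a small synthetic linked-claims universe.

Builds the five linked tables (person registry, billing claims,
discharge abstracts, ED records, physician registry) plus the
ground-truth continuity table, and prints their shapes and a few rows.
"""

from concare import SimulationConfig, generate_dataset

config = SimulationConfig(n_patients=1000, seed=42)
tables = generate_dataset(config)

for name, frame in tables.items():
    print(f"{name}: {frame.shape[0]} rows x {frame.shape[1]} cols")
print()
print(tables["claims"].head(5).to_string(index=False))
print()
truth = tables["truth"]
print(
    f"mean true COC {truth['true_coc'].mean():.3f} | "
    f"low-continuity fraction {truth['true_low_coci'].mean():.3f}"
)
# Every downstream stage is testable against this table: it holds each
# patient's true continuity indices and planted admission probability.
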