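"""Generate a synthetic drug-adaptation experiment and look at its anatomy.

Simulates two RTK-mechanism cell lines plus one NRAS-mechanism control,
each with parental / persistent / resistant states (3 replicates), and
plants four effect programs on disjoint protein sets.
"""

from adaptsig import SimulationConfig, simulate_experiment

cfg = SimulationConfig(n_proteins=400, seed=1, missing_midpoint=20.0)
table, sets, truth = simulate_experiment(cfg)

print(f"features (phospho-sites): {table.n_features}")
print(f"samples:                  {table.n_samples}")
print(f"missing values:           {table.n_missing} "
      f"({table.n_missing / table.values.size:.1%} of cells)")
print(f"gene sets emitted:        {len(sets)}")
for prog, members in truth.programs.items():
    print(f"  planted {prog:16s} {len(members)} proteins")

# the planted shared program carries a +2 log2 effect (4-fold) in BOTH the
# persistent and resistant states of the RTK lines, but not in the NRAS line
p = truth.programs["shared_up"][0]
for col in ("RTK1:persistent", "RTK1:resistant", "NRAS1:resistant"):
    print(f"  true effect of {p} in {col}: {truth.protein_effects.loc[p, col]:+.1f} log2")
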