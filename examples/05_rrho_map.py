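"""Rank-rank hypergeometric overlap between two fold-change rankings.

Each map cell asks how surprising the overlap between the top-i genes of
one ranking and the top-j of the other is; the map maximum locates the
strongest agreement region.
"""

from adaptsig import (
    Contrast,
    SimulationConfig,
    feature_ttest,
    make_expression_twin,
    rank_features,
    rrho_map,
    simulate_experiment,
)

_, _, truth = simulate_experiment(SimulationConfig(n_proteins=500, seed=4))
twin = make_expression_twin(truth)
ranks = {}
for line in ("RTK1", "RTK2"):
    d = feature_ttest(twin, Contrast(line, (line, "parental"), (line, "resistant")))
    ranks[line] = rank_features(d["log2fc"].dropna().to_dict())

m = rrho_map(ranks["RTK1"], ranks["RTK2"])
print(f"universe: {m.N} genes, grid {m.values.shape[0]} x {m.values.shape[1]} "
      f"(step {m.thresholds_a[0]})")
print(f"map maximum: -log10 p = {m.max_value:.1f} at thresholds {m.max_location}")
print("A maximum near the top-left corner means the genes most upregulated "
      "in one line are the same genes most upregulated in the other.")
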