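"""Pairwise signature correlation with hierarchical clustering.

Fold-change signatures of the two RTK-mechanism lines (and their sum)
should cluster together, away from the NRAS-mechanism control.
"""

from adaptsig import (
    Contrast,
    SimulationConfig,
    cut_clusters,
    feature_ttest,
    hierarchical_cluster,
    linkage_to_newick,
    make_expression_twin,
    pairwise_signature_correlation,
    simulate_experiment,
    sum_fold_change_signature,
)

_, _, truth = simulate_experiment(SimulationConfig(n_proteins=500, seed=5))
twin = make_expression_twin(truth)

sigs = {}
diffs = {}
for line in ("RTK1", "RTK2", "NRAS1"):
    d = feature_ttest(twin, Contrast(line, (line, "parental"), (line, "resistant")))
    diffs[line] = d
    sigs[line] = d["log2fc"].dropna()
sigs["RTK_sum"] = sum_fold_change_signature([diffs["RTK1"], diffs["RTK2"]]).as_series()

sm = hierarchical_cluster(pairwise_signature_correlation(sigs))
print("pairwise Pearson r:")
print(sm.correlations.round(2))
print("\nleaf order:", " ".join(sm.leaf_order))
print("clusters at k=2:", cut_clusters(sm, 2))
print("\nnewick:", linkage_to_newick(sm.linkage, sm.names))
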