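"""Direction-of-change concordance between two resistant cell lines.

Significant sites are cross-tabulated by fold-change sign; a heavy
diagonal (and a tiny Fisher p) means both lines rewire the same way.
"""

from adaptsig import (
    Contrast,
    SimulationConfig,
    build_direction_table,
    feature_ttest,
    fisher_exact_2x2,
    simulate_experiment,
)

table, _, _ = simulate_experiment(SimulationConfig(n_proteins=500, seed=2))
d1 = feature_ttest(table, Contrast("r1", ("RTK1", "parental"), ("RTK1", "resistant")))
d2 = feature_ttest(table, Contrast("r2", ("RTK2", "parental"), ("RTK2", "resistant")))

dt = build_direction_table(d1, d2, sig_policy="either", alpha=0.2)
print(dt.as_frame())
print(f"concordant fraction: {dt.concordant_fraction:.3f}")
print(f"Fisher's exact p:    {fisher_exact_2x2(dt):.3e}")
print("A diagonal table means the two lines share the direction of their "
      "phospho-signaling changes.")
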