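"""Run the whole pipeline on a synthetic experiment and read the summary.

Equivalent to `adaptsig pipeline --out scratch/example_pipeline`.
All stage outputs are plain text under the output directory.
"""

import json

from adaptsig import PipelineConfig, SimulationConfig, run_pipeline

cfg = PipelineConfig(
    sim=SimulationConfig(n_proteins=300, seed=7),
    signature_B=1000,
    gsea_B=500,
    top_k=40,
)
summary = run_pipeline(cfg, "scratch/example_pipeline")

print(json.dumps(
    {k: summary[k] for k in ("config_hash", "concordance", "signature_ks",
                             "specific_sets", "rrho", "recovery_at_k")},
    indent=2))
print("\nTop shared candidates:", ", ".join(summary["top_candidates_up"][:8]), "...")
print("recovery_at_k is the fraction of planted shared-program proteins "
      "found in the top-k of the combined perturbation score.")
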