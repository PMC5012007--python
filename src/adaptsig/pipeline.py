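"""End-to-end orchestration on synthetic experiments.

Runs the full integrative analysis in the order the stages build on each
other: simulate → normalize → per-contrast differential statistics →
direction concordance → signature / set enrichment with the specificity
filter → RRHO → signature correlation clustering → combined perturbation
score with planted-target recovery.  All intermediates are plain text
(TSV/GMT/JSON) so every stage can be inspected and re-run in isolation;
the summary JSON is stamped with the config hash and seed and is
byte-identical across runs with the same config.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .concordance import build_direction_table, fisher_exact_2x2
from .core import Contrast, DataError, rank_features, write_gmt, write_quant_table
from .differential import (
    FILTER_PRESETS,
    apply_filter,
    feature_ttest,
    normalize_median_center,
    sum_fold_change_signature,
)
from .enrichment import gsea_es_nes, kinase_enrichment, ks_permutation_test, specificity_filter
from .perturbation import combined_perturbation_score, recover_shared_targets
from .rrho import rrho_map
from .sigcompare import hierarchical_cluster, linkage_to_newick, pairwise_signature_correlation
from .simulate import SimulationConfig, make_expression_twin, simulate_experiment

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline"]


class PipelineError(RuntimeError):
    """A stage failure, attributed to the stage that raised it."""


@dataclass
class PipelineConfig:
    sim: SimulationConfig = field(default_factory=SimulationConfig)
    signature_B: int = 2000       # permutations for the KS signature test
    gsea_B: int = 1000            # permutations per set for GSEA / kinase runs
    rrho_step: int | None = None
    rrho_correction: str = "none"
    concordance_alpha: float = 0.2
    filter_preset: str = "phospho_fdr2_2fold"
    q_case: float = 0.1
    q_control: float = 0.2
    top_k: int = 40

    def validate(self) -> None:
        rtk = [cl for cl in self.sim.cell_lines if cl.mechanism == "RTK"]
        for cl in rtk[:2]:
            for st in ("parental", "persistent", "resistant"):
                if st not in cl.states:
                    raise PipelineError(
                        f"validation: cell line {cl.name!r} lacks state {st!r}"
                    )
        if len(rtk) < 2:
            raise PipelineError("validation: need >=2 RTK-mechanism cell lines")
        if self.filter_preset not in FILTER_PRESETS:
            raise PipelineError(f"validation: unknown filter preset {self.filter_preset!r}")
        if self.signature_B < 99 or self.gsea_B < 99:
            raise PipelineError("validation: permutation counts must be >= 99")

    def to_dict(self) -> dict:
        d = {k: getattr(self, k) for k in (
            "signature_B", "gsea_B", "rrho_step", "rrho_correction",
            "concordance_alpha", "filter_preset", "q_case", "q_control", "top_k",
        )}
        d["sim"] = self.sim.to_dict()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "sim" in d:
            d["sim"] = SimulationConfig.from_dict(d["sim"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError(f"stage {name!r}: {exc}") from exc
        return wrapped
    return deco


def _round(x: float, nd: int = 6) -> float:
    return float(np.round(float(x), nd))


def run_pipeline(config: PipelineConfig, out_dir: str | Path) -> dict:
    """Run every stage on a simulated experiment; return the summary dict.

    Deterministic given the config (all permutation seeds are derived from
    ``config.sim.seed``).  Writes stage outputs and ``summary.json`` under
    ``out_dir``.
    """
    config.validate()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg = config
    base_seed = cfg.sim.seed

    # -- simulate -------------------------------------------------------
    table, sets, truth = _stage("simulate")(simulate_experiment)(cfg.sim)
    write_quant_table(table, out / "phospho.tsv")
    write_gmt(sets, out / "genesets.gmt")
    truth.to_json(out / "truth.json")

    # -- normalize + differential --------------------------------------
    table = _stage("normalize")(normalize_median_center)(table)
    rtk = [cl.name for cl in cfg.sim.cell_lines if cl.mechanism == "RTK"][:2]
    contrasts = []
    for line in rtk:
        for st in ("resistant", "persistent"):
            contrasts.append(
                Contrast(f"{line}_{st[:3]}", (line, "parental"), (line, st))
            )
    diffs = {}
    for c in contrasts:
        diffs[c.name] = _stage("differential")(feature_ttest)(table, c)
        diffs[c.name].to_csv(out / f"diff_{c.name}.tsv", sep="\t")
    spec = FILTER_PRESETS[cfg.filter_preset]
    survivors = {
        name: int(apply_filter(d, spec).attrs["n_survivors"]) for name, d in diffs.items()
    }

    # -- concordance between the two resistant contrasts ----------------
    res_names = [c.name for c in contrasts if c.name.endswith("_res")]
    dt = _stage("concordance")(build_direction_table)(
        diffs[res_names[0]], diffs[res_names[1]], alpha=cfg.concordance_alpha
    )
    fisher_p = fisher_exact_2x2(dt)
    (out / "concordance.json").write_text(json.dumps({
        "counts": dt.counts.tolist(),
        "concordant_fraction": _round(dt.concordant_fraction),
        "fisher_p": fisher_p,
        "policy": dt.policy,
    }, sort_keys=True, indent=2))

    # -- expression twin: signature enrichment, specificity, RRHO -------
    twin = _stage("expression_twin")(make_expression_twin)(truth, cfg.sim)
    expr_diffs = {}
    lines = [cl.name for cl in cfg.sim.cell_lines if "resistant" in cl.states]
    for line in lines:
        c = Contrast(f"{line}_expr", (line, "parental"), (line, "resistant"))
        expr_diffs[line] = feature_ttest(twin, c)
    sum_rank = sum_fold_change_signature([expr_diffs[l] for l in rtk])
    mes = sets.members("resistant_up")
    ks = _stage("ks_signature")(ks_permutation_test)(
        sum_rank, mes, B=cfg.signature_B, seed=base_seed + 101, set_name="resistant_up"
    )

    protein_sets = sets.subset(
        [n for n in sets.names() if not n.startswith("substrates_")]
    )
    gsea_by_line = {}
    for i, line in enumerate(lines):
        ranked = rank_features(expr_diffs[line]["log2fc"].dropna().to_dict())
        gsea_by_line[line] = gsea_es_nes(
            ranked, protein_sets, B=cfg.gsea_B, seed=base_seed + 201 + i
        )
        gsea_by_line[line].drop(columns=["leading_edge"]).to_csv(
            out / f"gsea_{line}.tsv", sep="\t"
        )
    nras = [cl.name for cl in cfg.sim.cell_lines if cl.mechanism == "NRAS"]
    if nras and nras[0] in gsea_by_line:
        specific = _stage("specificity_filter")(specificity_filter)(
            [gsea_by_line[l] for l in rtk], gsea_by_line[nras[0]],
            q_case=cfg.q_case, q_control=cfg.q_control,
        )
    else:
        specific = pd.DataFrame(columns=["sum_nes"])
    specific.to_csv(out / "specific_sets.tsv", sep="\t")

    rank_a = rank_features(expr_diffs[rtk[0]]["log2fc"].dropna().to_dict())
    rank_b = rank_features(expr_diffs[rtk[1]]["log2fc"].dropna().to_dict())
    rmap = _stage("rrho")(rrho_map)(
        rank_a, rank_b, step=cfg.rrho_step, correction=cfg.rrho_correction
    )
    pd.DataFrame(
        rmap.values, index=rmap.thresholds_a, columns=rmap.thresholds_b
    ).to_csv(out / "rrho_map.tsv", sep="\t")

    # -- signature correlation clustering -------------------------------
    sigs = {f"{l}_expr": expr_diffs[l]["log2fc"].dropna() for l in lines}
    sigs["sum_rtk"] = sum_rank.as_series()
    sm = _stage("signature_compare")(pairwise_signature_correlation)(sigs)
    sm = hierarchical_cluster(sm)
    sm.correlations.to_csv(out / "signature_correlations.tsv", sep="\t")
    (out / "signature_tree.nwk").write_text(
        linkage_to_newick(sm.linkage, sm.names) + "\n"
    )

    # -- kinase enrichment on the mean resistant fold change -------------
    fc_mean = pd.concat(
        [diffs[n]["log2fc"] for n in res_names], axis=1
    ).mean(axis=1, skipna=False).dropna()
    kin_input = pd.DataFrame({"log2fc": fc_mean})
    substrate_sets = sets.subset([n for n in sets.names() if n.startswith("substrates_")])
    kin = _stage("kinase_enrichment")(kinase_enrichment)(
        kin_input, substrate_sets, B=cfg.gsea_B, seed=base_seed + 301
    )
    kin.drop(columns=["leading_edge"]).to_csv(out / "kinase_enrichment.tsv", sep="\t")

    # -- combined perturbation score -------------------------------------
    scores = _stage("perturbation")(combined_perturbation_score)(
        [diffs[c.name] for c in contrasts]
    )
    scores.protein_table.to_csv(out / "perturbation_scores.tsv", sep="\t")
    k = min(cfg.top_k, len(scores.protein_table))
    recovery = recover_shared_targets(scores, truth, k=k)

    summary = {
        "config_hash": cfg.config_hash(),
        "seed": base_seed,
        "n_features": table.n_features,
        "n_missing": table.n_missing,
        "filter_survivors": survivors,
        "concordance": {
            "counts": dt.counts.tolist(),
            "concordant_fraction": _round(dt.concordant_fraction),
            "fisher_p_log10": _round(np.log10(max(fisher_p, 1e-320))),
        },
        "signature_ks": {"D": _round(ks.stat), "p": ks.p, "B": ks.n_perm},
        "specific_sets": list(specific.index),
        "rrho": {k2: (_round(v) if isinstance(v, float) else v) for k2, v in rmap.summary().items()},
        "signature_leaf_order": sm.leaf_order,
        "kinases_passing": sorted(kin.index[kin["passes"]]),
        "top_candidates_up": scores.top_candidates(k),
        "recovery_at_k": {"k": k, "fraction": _round(recovery)},
    }
    (out / "summary.json").write_text(json.dumps(summary, sort_keys=True, indent=2) + "\n")
    return summary
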