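"""Combined perturbation score across adaptation-state contrasts.

The headline statistic of the pipeline: per phospho-site, the signed log-t
scores s = sign(log2fc)·(−log10 p) from each contrast (two resistant/
parental and two persistent/parental pairs in the reference design) are
summed to S; sites are collapsed per protein by the largest |S| (sign
preserved), and proteins are ranked by S to surface alterations shared
between the early-persistent and late-resistant states (shared-up and
shared-down reported as separate directional rankings).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import DataError, RankedList
from .differential import collapse_to_protein
from .simulate import GroundTruth

__all__ = ["PerturbationScores", "combined_perturbation_score", "recover_shared_targets"]


@dataclass
class PerturbationScores:
    """Site- and protein-level summed score tables plus directional rankings.

    ``site_table`` has one s column per contrast, the sum S and coverage;
    ``protein_table`` carries the collapsed score, the provenance site, and
    the shared-up rank (1 = strongest shared upregulation).
    """

    site_table: pd.DataFrame
    protein_table: pd.DataFrame
    up_ranking: RankedList
    down_ranking: RankedList
    coverage_policy: str

    def top_candidates(self, k: int, direction: str = "up") -> list[str]:
        ranking = self.up_ranking if direction == "up" else self.down_ranking
        if k > len(ranking):
            raise DataError(f"k={k} exceeds table size {len(ranking)}")
        return ranking.ids[:k]


def combined_perturbation_score(
    diffs: list[pd.DataFrame],
    coverage_policy: str = "allow_missing",
) -> PerturbationScores:
    """Sum per-site signed log-t scores over ≥2 contrasts and collapse.

    ``allow_missing`` (default) sums over the contrasts in which a site
    was tested and flags incomplete coverage; such sites are down-weighted
    in tie-breaks (equal S ranks the fuller-coverage site first) but never
    dropped.  ``require_all`` keeps only sites tested in every contrast.
    """
    if len(diffs) < 2:
        raise DataError("combined perturbation score needs >=2 contrasts")
    if coverage_policy not in ("allow_missing", "require_all"):
        raise ValueError(f"unknown coverage policy {coverage_policy!r}")

    names = []
    for i, d in enumerate(diffs):
        name = d.attrs.get("contrast", f"contrast{i}")
        names.append(name)
    s_cols = pd.concat(
        [d["s"].rename(f"s_{n}") for d, n in zip(diffs, names)], axis=1
    )
    meta = pd.concat([d[["protein_id", "site_label"]] for d in diffs])
    meta = meta[~meta.index.duplicated()]

    n_present = s_cols.notna().sum(axis=1)
    if coverage_policy == "require_all":
        keep = n_present == len(diffs)
        s_cols = s_cols.loc[keep]
        n_present = n_present.loc[keep]
    else:
        keep = n_present >= 1
        s_cols = s_cols.loc[keep]
        n_present = n_present.loc[keep]
    if s_cols.empty:
        raise DataError("no sites with scores under the coverage policy")

    site = s_cols.copy()
    site["S"] = s_cols.sum(axis=1, skipna=True)
    site["n_contrasts_present"] = n_present
    site["coverage_flag"] = n_present < len(diffs)
    site["protein_id"] = meta.loc[site.index, "protein_id"]
    site["site_label"] = meta.loc[site.index, "site_label"]

    prot = collapse_to_protein(site, score_col="S")
    prot = prot.rename(columns={"score": "S"})
    cov = site.groupby("protein_id")["n_contrasts_present"].max()
    prot["n_contrasts_present"] = cov.loc[prot.index]

    # rank: S desc, fuller coverage first on ties, then protein id
    key = sorted(
        prot.index,
        key=lambda p: (-prot.loc[p, "S"], -prot.loc[p, "n_contrasts_present"], p),
    )
    prot = prot.loc[key]
    prot["rank_up"] = np.arange(1, len(prot) + 1)
    prot["rank_down"] = len(prot) - prot["rank_up"] + 1

    up = RankedList(
        ids=list(prot.index),
        scores=prot["S"].to_numpy(dtype=float),
    )
    down_ids = list(prot.index[::-1])
    down = RankedList(ids=down_ids, scores=-prot["S"].to_numpy(dtype=float)[::-1])
    return PerturbationScores(
        site_table=site,
        protein_table=prot,
        up_ranking=up,
        down_ranking=down,
        coverage_policy=coverage_policy,
    )


def recover_shared_targets(
    scores: PerturbationScores,
    truth: GroundTruth,
    k: int,
    program: str = "shared_up",
    direction: str = "up",
) -> float:
    """Fraction of a planted program's proteins found in the top-k ranking."""
    planted = set(truth.programs[program])
    if not planted:
        raise DataError(f"program {program!r} is empty")
    top = set(scores.top_candidates(k, direction=direction))
    return len(planted & top) / len(planted)
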