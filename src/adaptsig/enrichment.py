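"""Rank-based gene-set enrichment.

Two related statistics over a fixed ranked list:

* :func:`ks_permutation_test` — one-sided Kolmogorov–Smirnov rank test:
  D is the maximal excess of the signature's ECDF over the uniform
  background ECDF along the ranking (top-enrichment orientation), with a
  gene-label permutation p-value.
* :func:`gsea_es_nes` — GSEA-style running-sum enrichment score (optionally
  score-weighted), normalized by same-sign permutation means (NES), with BH
  q across sets and leading-edge extraction.

Permutations draw random member positions without replacement (gene-label
permutation on the fixed ranking), deterministic given ``seed``; the
add-one estimator keeps p ≥ 1/(B+1).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .core import DataError, GeneSetCollection, RankedList, rank_features

__all__ = [
    "EnrichmentResult",
    "ks_permutation_test",
    "gsea_es_nes",
    "specificity_filter",
    "kinase_enrichment",
]


@dataclass
class EnrichmentResult:
    set_name: str
    stat: float  # KS D or ES
    p: float
    nes: float | None = None
    q: float | None = None
    leading_edge: tuple[str, ...] = field(default_factory=tuple)
    n_members: int = 0
    n_perm: int = 0
    seed: int | None = None
    flag: str = ""


def _sample_positions(rng: np.random.Generator, n: int, m: int, b: int) -> np.ndarray:
    """B × m sorted random positions in [0, n), rows without replacement."""
    if m > n:
        raise ValueError("set larger than universe")
    if m * m <= n:  # collisions rare: rejection sampling
        pos = np.sort(rng.integers(0, n, size=(b, m)), axis=1)
        bad = np.flatnonzero((np.diff(pos, axis=1) == 0).any(axis=1))
        while bad.size:
            pos[bad] = np.sort(rng.integers(0, n, size=(bad.size, m)), axis=1)
            bad = np.flatnonzero((np.diff(pos, axis=1) == 0).any(axis=1))
        return pos
    # dense sets: chunked partial permutations
    out = np.empty((b, m), dtype=np.int64)
    chunk = max(1, int(2e6 // max(n, 1)))
    base = np.arange(n)
    for start in range(0, b, chunk):
        rows = min(chunk, b - start)
        block = rng.permuted(np.tile(base, (rows, 1)), axis=1)[:, :m]
        out[start : start + rows] = np.sort(block, axis=1)
    return out


def _ks_d(pos: np.ndarray, n: int) -> np.ndarray:
    """One-sided KS D per row of sorted 0-based member positions."""
    m = pos.shape[-1]
    j = np.arange(1, m + 1)
    return ((j / m) - (pos + 1) / n).max(axis=-1)


def ks_permutation_test(
    ranked: RankedList,
    geneset: frozenset[str] | set[str],
    B: int = 10000,
    seed: int | None = None,
    set_name: str = "",
    side: str = "top",
) -> EnrichmentResult:
    """Permutation KS test for enrichment of a set at one end of a ranking.

    ``side="top"`` tests over-representation among the highest-scoring
    identifiers; ``side="bottom"`` reverses the list first.  Requires
    B ≥ 99 permutations.
    """
    if B < 99:
        raise ValueError("B must be >= 99")
    if side == "bottom":
        ranked = ranked.reversed()
    elif side != "top":
        raise ValueError(f"unknown side {side!r}")
    n = len(ranked)
    members = frozenset(geneset) & set(ranked.ids)
    if not members:
        raise DataError("gene set does not intersect the ranked universe")
    if len(members) == n:
        return EnrichmentResult(
            set_name=set_name, stat=0.0, p=1.0, n_members=n, n_perm=B, seed=seed,
            flag="set_equals_universe",
        )
    id_index = {ident: i for i, ident in enumerate(ranked.ids)}
    pos = np.sort(np.array([id_index[g] for g in members]))
    m = len(pos)
    d_obs = float(_ks_d(pos, n))

    rng = np.random.default_rng(seed)
    d_perm = _ks_d(_sample_positions(rng, n, m, B), n)
    p = (np.count_nonzero(d_perm >= d_obs) + 1) / (B + 1)

    j = np.arange(1, m + 1)
    peak = int(np.argmax(j / m - (pos + 1) / n))
    leading = tuple(ranked.ids[i] for i in pos[: peak + 1])
    return EnrichmentResult(
        set_name=set_name, stat=d_obs, p=float(p), leading_edge=leading,
        n_members=m, n_perm=B, seed=seed,
    )


def _es_from_positions(pos: np.ndarray, absw: np.ndarray, n: int) -> tuple[np.ndarray, np.ndarray]:
    """Signed ES and peak member index per row of sorted positions.

    ``absw`` are the |score|^weight increments over the full list; the
    running sum gains the member's normalized weight at a hit and loses
    1/(N−m) at a miss.  Candidate extrema occur just after (maxima) or
    just before (minima) each member.
    """
    if pos.ndim == 1:
        pos = pos[None, :]
    b, m = pos.shape
    w = absw[pos]
    tot = w.sum(axis=1, keepdims=True)
    uniform = tot == 0  # all-zero scores: fall back to unweighted hits
    w = np.where(uniform, 1.0, w)
    tot = np.where(uniform, float(m), tot)
    hit_after = np.cumsum(w, axis=1) / tot
    hit_before = hit_after - w / tot
    j = np.arange(m)
    miss = (pos - j) / (n - m)
    run_after = hit_after - miss
    run_before = hit_before - miss
    es_pos = np.maximum(run_after.max(axis=1), 0.0)
    es_neg = np.minimum(run_before.min(axis=1), 0.0)
    es = np.where(es_pos >= -es_neg, es_pos, es_neg)
    peak = np.where(
        es_pos >= -es_neg, run_after.argmax(axis=1), run_before.argmin(axis=1)
    )
    return es, peak


def gsea_es_nes(
    ranked: RankedList,
    sets: GeneSetCollection,
    B: int = 1000,
    seed: int | None = None,
    weight: float = 1.0,
    min_size: int = 3,
) -> pd.DataFrame:
    """Running-sum ES/NES for every set in a collection.

    ``weight=0`` is the classic (unweighted) KS walk; ``weight=1`` weights
    hit increments by |score|.  NES normalizes ES by the mean |ES*| of
    same-sign permutations; p uses same-sign permutations with the add-one
    estimator; q is BH across scored sets.  Sets smaller than ``min_size``
    (after intersection with the universe) are skipped with a record.
    """
    if weight < 0:
        raise ValueError("weight must be >= 0")
    n = len(ranked)
    id_index = {ident: i for i, ident in enumerate(ranked.ids)}
    absw = np.abs(ranked.scores) ** weight if weight > 0 else np.ones(n)

    rng = np.random.default_rng(seed)
    rows = []
    for name in sets.names():
        members = [g for g in sets.sets[name] if g in id_index]
        m = len(members)
        if m < min_size or m >= n:
            rows.append(
                {"set_name": name, "es": np.nan, "nes": np.nan, "p": np.nan,
                 "size": m, "leading_edge": (), "flag": "too_small" if m < min_size else "set_equals_universe"}
            )
            continue
        pos = np.sort(np.array([id_index[g] for g in members]))
        es_obs, peak = _es_from_positions(pos, absw, n)
        es_obs = float(es_obs[0])
        peak = int(peak[0])
        es_perm, _ = _es_from_positions(_sample_positions(rng, n, m, B), absw, n)
        if es_obs > 0:
            same = es_perm[es_perm > 0]
            p = (np.count_nonzero(es_perm >= es_obs) + 1) / (len(same) + 1)
            nes = es_obs / same.mean() if len(same) else np.nan
            leading = tuple(ranked.ids[i] for i in pos[: peak + 1])
        elif es_obs < 0:
            same = es_perm[es_perm < 0]
            p = (np.count_nonzero(es_perm <= es_obs) + 1) / (len(same) + 1)
            nes = es_obs / np.abs(same.mean()) if len(same) else np.nan
            leading = tuple(ranked.ids[i] for i in pos[peak:])
        else:
            p, nes, leading = 1.0, 0.0, ()
        rows.append(
            {"set_name": name, "es": es_obs, "nes": nes, "p": min(float(p), 1.0),
             "size": m, "leading_edge": leading, "flag": ""}
        )
    df = pd.DataFrame(rows).set_index("set_name")
    df["q"] = np.nan
    scored = df["p"].notna()
    if scored.any():
        df.loc[scored, "q"] = multipletests(df.loc[scored, "p"], method="fdr_bh")[1]
    df.attrs["B"] = B
    df.attrs["seed"] = seed
    df.attrs["weight"] = weight
    return df


def specificity_filter(
    case_results: list[pd.DataFrame],
    control_results: pd.DataFrame,
    q_case: float = 0.1,
    q_control: float = 0.2,
) -> pd.DataFrame:
    """Sets significant in every case collection but not in the control.

    Keeps sets with q < ``q_case`` in ALL case collections and
    q > ``q_control`` in the control collection, ordered by the summed
    case NES (descending).  Sets missing (or unscored) in any collection
    are excluded and recorded in ``attrs["excluded"]``.
    """
    if len(case_results) < 2:
        raise DataError("specificity filter needs >=2 case collections")
    all_names = set(case_results[0].index)
    excluded: list[str] = []
    rows = []
    for name in sorted(all_names):
        qs, ness = [], []
        missing = False
        for res in [*case_results, control_results]:
            if name not in res.index or not np.isfinite(res.loc[name, "p"]):
                missing = True
                break
        if missing:
            excluded.append(name)
            continue
        qs = [float(res.loc[name, "q"]) for res in case_results]
        ness = [float(res.loc[name, "nes"]) for res in case_results]
        q_ctrl = float(control_results.loc[name, "q"])
        if all(q < q_case for q in qs) and q_ctrl > q_control:
            rows.append(
                {"set_name": name, "sum_nes": sum(ness), "q_control": q_ctrl}
                | {f"q_case_{i}": q for i, q in enumerate(qs)}
                | {f"nes_case_{i}": v for i, v in enumerate(ness)}
            )
    out = (
        pd.DataFrame(rows).set_index("set_name").sort_values("sum_nes", ascending=False)
        if rows
        else pd.DataFrame(columns=["sum_nes", "q_control"])
    )
    out.attrs["excluded"] = excluded
    return out


def kinase_enrichment(
    diff: pd.DataFrame,
    substrate_sets: GeneSetCollection,
    B: int = 1000,
    seed: int | None = None,
    max_q: float = 0.2,
    weight: float = 1.0,
) -> pd.DataFrame:
    """Kinase-substrate enrichment on a fold-change ranking of phospho-sites.

    Sites are ranked by log2 fold change; each kinase's substrate-site set
    is scored with :func:`gsea_es_nes`.  ``passes`` marks kinases at
    q < ``max_q``.  Empty (non-intersecting) substrate sets are skipped
    with a record (flag column).
    """
    fc = diff["log2fc"].dropna()
    if fc.empty:
        raise DataError("no fold changes to rank")
    ranked = rank_features(fc.to_dict())
    res = gsea_es_nes(ranked, substrate_sets, B=B, seed=seed, weight=weight)
    res["passes"] = (res["q"] < max_q).fillna(False)
    return res
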