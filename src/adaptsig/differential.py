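"""Per-feature differential statistics, filters and summarization.

Differential results are returned as DataFrames indexed by ``feature_id``
with columns::

    protein_id, site_label, log2fc, stat, p, q, s, n_a, n_b, flag

* ``log2fc`` is mean(group_b) − mean(group_a) on the log2 scale.
* ``stat`` is the pooled-variance Student t of group_a vs group_b (so a
  positive fold change has a negative t); direction is always read from
  ``log2fc``.
* ``q`` is the Benjamini–Hochberg adjusted p over tested features.
* ``s`` is the signed log-t score sign(log2fc)·(−log10 p), capped at ±300;
  it is the per-contrast ingredient of the combined perturbation score.

Features with fewer than two present replicates in either group are kept
in the table with NaN statistics and flag ``insufficient_replicates``;
zero pooled variance with unequal means gets the sentinel p floor and
flag ``zero_variance``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .core import Contrast, DataError, QuantTable, RankedList, rank_features

__all__ = [
    "FilterSpec",
    "FILTER_PRESETS",
    "normalize_median_center",
    "feature_ttest",
    "feature_anova",
    "apply_filter",
    "protein_summarize",
    "collapse_to_protein",
    "signed_t_order",
    "sum_fold_change_signature",
    "signed_log_t",
]

P_FLOOR = 1e-300
S_CAP = 300.0


@dataclass(frozen=True)
class FilterSpec:
    """Significance + fold-change filter.

    ``min_abs_fold`` is on the linear scale (2 means 2-fold up OR down).
    ``use_raw_p`` selects the raw p column instead of BH q — the ANOVA
    proteome filter is defined on raw p, the t-test phospho filter on q.
    """

    max_q: float
    min_abs_fold: float = 1.0
    test: str = "student_t"  # or "anova"
    use_raw_p: bool = False

    def __post_init__(self) -> None:
        if not (0 < self.max_q <= 1):
            raise ValueError("max_q must be in (0, 1]")
        if self.min_abs_fold < 1:
            raise ValueError("min_abs_fold must be >= 1")
        if self.test not in ("student_t", "anova"):
            raise ValueError(f"unknown test {self.test!r}")


#: Named threshold presets: ANOVA raw p<0.05 with average 3-fold change
#: (whole-proteome state comparison), Student t BH q<0.2 with 2-fold change
#: (persistent phospho-profile), and BH q<0.1 (ECM protein profile).
FILTER_PRESETS: dict[str, FilterSpec] = {
    "proteome_anova_3fold": FilterSpec(max_q=0.05, min_abs_fold=3.0, test="anova", use_raw_p=True),
    "phospho_fdr2_2fold": FilterSpec(max_q=0.2, min_abs_fold=2.0, test="student_t"),
    "ecm_fdr1": FilterSpec(max_q=0.1, min_abs_fold=1.0, test="student_t"),
}


def normalize_median_center(table: QuantTable) -> QuantTable:
    """Subtract each sample column's median (over present values).

    Idempotent; the missing mask is unchanged.  Requires log2 scale and at
    least two present values per column.
    """
    if table.scale != "log2":
        raise DataError("median centering requires log2 scale")
    counts = table.values.notna().sum(axis=0)
    if (counts < 2).any():
        bad = list(counts.index[counts < 2])
        raise DataError(f"column(s) with <2 present values: {bad}")
    med = table.values.median(axis=0, skipna=True)
    return QuantTable(
        values=table.values - med,
        feature_meta=table.feature_meta,
        sample_meta=table.sample_meta,
        scale="log2",
    )


def signed_log_t(log2fc: np.ndarray, p: np.ndarray, stat: np.ndarray, mode: str = "log_p") -> np.ndarray:
    """Signed significance score.

    ``log_p`` (default): sign(log2fc)·(−log10 p);  ``log_t``:
    sign(log2fc)·log10(1+|t|).  Both are capped at ±300 so sums stay finite.
    """
    sign = np.sign(log2fc)
    if mode == "log_p":
        mag = -np.log10(np.maximum(p, P_FLOOR))
    elif mode == "log_t":
        mag = np.log10(1.0 + np.abs(stat))
    else:
        raise ValueError(f"unknown score mode {mode!r}")
    return np.clip(sign * mag, -S_CAP, S_CAP)


def _group_stats(x: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Row-wise n, mean, var (ddof=1) ignoring NaN; mean/var NaN where undefined."""
    present = ~np.isnan(x)
    n = present.sum(axis=1)
    sums = np.where(present, x, 0.0).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = sums / n
    dev2 = np.where(present, np.square(x - mean[:, None]), 0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        var = dev2.sum(axis=1) / (n - 1)
    var[n < 2] = np.nan
    mean[n == 0] = np.nan
    return n.astype(np.int64), mean, var


def feature_ttest(
    table: QuantTable,
    contrast: Contrast,
    equal_var: bool = True,
    score_mode: str = "log_p",
) -> pd.DataFrame:
    """Two-sided per-feature Student's t-test for a two-group contrast.

    Pooled-variance by default (``equal_var=False`` gives Welch).  BH q is
    computed across the tested features only.
    """
    samples_a, samples_b = contrast.resolve(table)
    xa = table.values[samples_a].to_numpy(dtype=float)
    xb = table.values[samples_b].to_numpy(dtype=float)

    na, ma, va = _group_stats(xa)
    nb, mb, vb = _group_stats(xb)
    log2fc = mb - ma

    tested = (na >= 2) & (nb >= 2)
    t = np.full(len(log2fc), np.nan)
    p = np.full(len(log2fc), np.nan)
    flag = np.where(tested, "", "insufficient_replicates").astype(object)

    if tested.any():
        va_t, vb_t = va[tested], vb[tested]
        na_t, nb_t = na[tested], nb[tested]
        diff_ab = ma[tested] - mb[tested]  # t-statistic convention: a vs b
        if equal_var:
            df = na_t + nb_t - 2
            sp2 = ((na_t - 1) * va_t + (nb_t - 1) * vb_t) / df
            se = np.sqrt(sp2 * (1.0 / na_t + 1.0 / nb_t))
        else:
            se2a, se2b = va_t / na_t, vb_t / nb_t
            se = np.sqrt(se2a + se2b)
            with np.errstate(invalid="ignore", divide="ignore"):
                df = (se2a + se2b) ** 2 / (
                    se2a**2 / (na_t - 1) + se2b**2 / (nb_t - 1)
                )
        with np.errstate(invalid="ignore", divide="ignore"):
            t_t = diff_ab / se
        p_t = np.empty_like(t_t)
        zero_se = se == 0
        # identical groups with zero variance: t=0, p=1
        t_t[zero_se & (diff_ab == 0)] = 0.0
        p_t[zero_se & (diff_ab == 0)] = 1.0
        # zero variance, unequal means: sentinel
        zv = zero_se & (diff_ab != 0)
        t_t[zv] = np.sign(diff_ab[zv]) * np.inf
        p_t[zv] = P_FLOOR
        ok = ~zero_se
        p_t[ok] = 2.0 * stats.t.sf(np.abs(t_t[ok]), df[ok] if np.ndim(df) else df)
        p_t = np.maximum(p_t, P_FLOOR)
        t[tested] = t_t
        p[tested] = p_t
        fl = flag[tested]
        fl[zv] = "zero_variance"
        flag[tested] = fl

    q = np.full(len(p), np.nan)
    if tested.any():
        q[tested] = multipletests(p[tested], method="fdr_bh")[1]

    s = np.full(len(p), np.nan)
    s[tested] = signed_log_t(log2fc[tested], p[tested], t[tested], mode=score_mode)

    res = pd.DataFrame(
        {
            "protein_id": table.feature_meta["protein_id"].to_numpy(),
            "site_label": table.feature_meta["site_label"].to_numpy(),
            "log2fc": log2fc,
            "stat": t,
            "p": p,
            "q": q,
            "s": s,
            "n_a": na,
            "n_b": nb,
            "flag": flag,
        },
        index=table.values.index,
    )
    res.attrs["contrast"] = contrast.name
    res.attrs["test"] = "student_t" if equal_var else "welch_t"
    return res


def feature_anova(
    table: QuantTable,
    groups: list[tuple[str | None, str]],
    fold_pair: tuple[int, int] = (0, 1),
) -> pd.DataFrame:
    """One-way ANOVA across ≥3 groups, per feature.

    ``log2fc`` reports the group-mean difference for ``fold_pair``
    (defaults to group 1 vs group 0, e.g. persistent vs parental); all
    pairwise mean differences vs group 0 are included as
    ``log2fc_<group>`` columns.
    """
    if len(groups) < 3:
        raise DataError("ANOVA requires >=3 groups")
    group_samples = [table.select(*g) for g in groups]
    for g, s in zip(groups, group_samples):
        if len(s) < 2:
            raise DataError(f"group {g} resolves to <2 samples")
    mats = [table.values[s].to_numpy(dtype=float) for s in group_samples]
    ns, means, vars_ = zip(*(_group_stats(m) for m in mats))
    ns = np.stack(ns)         # k x features
    means = np.stack(means)
    vars_ = np.stack(vars_)

    tested = np.all(ns >= 2, axis=0)
    k = len(groups)
    N = ns.sum(axis=0)
    grand = np.sum(ns * means, axis=0) / N
    ssb = np.sum(ns * (means - grand) ** 2, axis=0)
    ssw = np.sum((ns - 1) * vars_, axis=0)
    F = np.full(len(N), np.nan)
    p = np.full(len(N), np.nan)
    flag = np.where(tested, "", "insufficient_replicates").astype(object)
    if tested.any():
        dfb = k - 1
        dfw = N[tested] - k
        msb = ssb[tested] / dfb
        msw = ssw[tested] / dfw
        with np.errstate(invalid="ignore", divide="ignore"):
            F_t = msb / msw
        p_t = np.empty_like(F_t)
        zero = msw == 0
        F_t[zero & (msb == 0)] = 0.0
        p_t[zero & (msb == 0)] = 1.0
        zv = zero & (msb > 0)
        F_t[zv] = np.inf
        p_t[zv] = P_FLOOR
        ok = ~zero
        p_t[ok] = stats.f.sf(F_t[ok], dfb, dfw[ok])
        p_t = np.maximum(p_t, P_FLOOR)
        F[tested] = F_t
        p[tested] = p_t
        fl = flag[tested]
        fl[zv] = "zero_variance"
        flag[tested] = fl

    q = np.full(len(p), np.nan)
    if tested.any():
        q[tested] = multipletests(p[tested], method="fdr_bh")[1]

    i0, i1 = fold_pair
    log2fc = means[i1] - means[i0]
    s = np.full(len(p), np.nan)
    s[tested] = signed_log_t(log2fc[tested], p[tested], F[tested])

    res = pd.DataFrame(
        {
            "protein_id": table.feature_meta["protein_id"].to_numpy(),
            "site_label": table.feature_meta["site_label"].to_numpy(),
            "log2fc": log2fc,
            "stat": F,
            "p": p,
            "q": q,
            "s": s,
            "n_a": ns[i0],
            "n_b": ns[i1],
            "flag": flag,
        },
        index=table.values.index,
    )
    for gi in range(1, k):
        name = f"{groups[gi][0]}:{groups[gi][1]}" if groups[gi][0] else groups[gi][1]
        res[f"log2fc_{name}"] = means[gi] - means[0]
    res.attrs["test"] = "anova"
    res.attrs["groups"] = [f"{g[0]}:{g[1]}" for g in groups]
    return res


def apply_filter(result: pd.DataFrame, spec: FilterSpec) -> pd.DataFrame:
    """Subset of features passing the significance + fold filter.

    Significance uses q (BH) unless ``spec.use_raw_p``; fold passes when
    ``|log2fc| >= log2(min_abs_fold)``.  Untested features never pass.
    """
    test = result.attrs.get("test", "student_t")
    if spec.test == "anova" and test != "anova":
        raise DataError(f"filter expects ANOVA results, got {test!r}")
    if spec.test == "student_t" and test == "anova":
        raise DataError("filter expects t-test results, got ANOVA")
    col = "p" if spec.use_raw_p else "q"
    sig = result[col] < spec.max_q
    fold = result["log2fc"].abs() >= np.log2(spec.min_abs_fold)
    mask = sig.fillna(False) & fold.fillna(False)
    out = result.loc[mask]
    out.attrs.update(result.attrs)
    out.attrs["n_survivors"] = int(mask.sum())
    out.attrs["filter"] = spec
    return out


def protein_summarize(table: QuantTable) -> QuantTable:
    """Protein-level table: median of mean-centered peptide rows.

    Each peptide row is centered by its own mean over present values;
    the protein value per sample is the median over that protein's
    centered peptides (midpoint for even counts).  Invariant to peptide
    duplication and (after centering) to per-peptide constant shifts.
    """
    if table.scale != "log2":
        raise DataError("protein summarization requires log2 scale")
    centered = table.values.sub(table.values.mean(axis=1, skipna=True), axis=0)
    prot = table.feature_meta["protein_id"]
    med = centered.groupby(prot.to_numpy()).median()
    med.index.name = "feature_id"
    fmeta = pd.DataFrame(
        {"protein_id": med.index, "site_label": [""] * len(med)}, index=med.index
    )
    return QuantTable(values=med, feature_meta=fmeta, sample_meta=table.sample_meta, scale="log2")


def collapse_to_protein(site_scores: pd.DataFrame, score_col: str = "S") -> pd.DataFrame:
    """Per-protein score: the site with the largest absolute score.

    Tie-break on |score|: prefer the positive score, then the
    lexicographically smallest site label; ties are flagged in
    ``tie_flag``.  Requires columns ``protein_id``, ``site_label`` and
    ``score_col``; rows with NaN scores are dropped (a protein with no
    scored sites is an error).
    """
    df = site_scores.dropna(subset=[score_col])
    if df.empty:
        raise DataError("no scored sites to collapse")
    rows = []
    for prot, grp in df.groupby("protein_id", sort=True):
        scores = grp[score_col].to_numpy(dtype=float)
        labels = grp["site_label"].astype(str).to_numpy()
        feats = grp.index.to_numpy()
        amax = np.abs(scores).max()
        cand = np.flatnonzero(np.abs(scores) == amax)
        tie = len(cand) > 1
        if tie and np.any(scores[cand] > 0):
            cand = cand[scores[cand] > 0]
        # lexicographic site label among remaining candidates
        best = cand[np.argsort(labels[cand], kind="stable")[0]]
        rows.append(
            {
                "protein_id": prot,
                "score": scores[best],
                "site_label": labels[best],
                "feature_id": feats[best],
                "n_sites": len(grp),
                "tie_flag": tie,
            }
        )
    out = pd.DataFrame(rows).set_index("protein_id")
    return out


def signed_t_order(result: pd.DataFrame) -> RankedList:
    """Rank features by the signed t statistic, sign taken from log2fc.

    Score = sign(log2fc)·|t|, descending; untested features are excluded.
    """
    df = result.dropna(subset=["stat"])
    score = np.sign(df["log2fc"].to_numpy()) * np.abs(df["stat"].to_numpy())
    # infinities from zero-variance sentinels sort to the extremes
    score = np.where(np.isposinf(score), 1e308, np.where(np.isneginf(score), -1e308, score))
    return rank_features(dict(zip(df.index, score)))


def sum_fold_change_signature(
    results: list[pd.DataFrame], join: str = "intersection"
) -> RankedList:
    """Per-feature sum of log2 fold changes across ≥1 contrasts, ranked.

    ``join="intersection"`` (default) restricts to features tested in all
    contrasts; ``join="union"`` sums over present contrasts.
    """
    if not results:
        raise DataError("need at least one differential result")
    series = [r["log2fc"].dropna() for r in results]
    if join == "intersection":
        idx = series[0].index
        for s in series[1:]:
            idx = idx.intersection(s.index)
        if len(idx) == 0:
            raise DataError("empty feature intersection across contrasts")
        total = sum(s.loc[idx] for s in series)
    elif join == "union":
        total = pd.concat(series, axis=1).sum(axis=1, skipna=True)
    else:
        raise ValueError(f"unknown join {join!r}")
    return rank_features(total.to_dict())
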