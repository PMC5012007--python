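"""Differential statistics: closed forms, filters, summarization, ranking."""

import numpy as np
import pandas as pd
import pytest

from adaptsig import (
    Contrast,
    FilterSpec,
    apply_filter,
    collapse_to_protein,
    feature_anova,
    feature_ttest,
    normalize_median_center,
    protein_summarize,
    signed_t_order,
    sum_fold_change_signature,
)
from adaptsig.core import DataError
from adaptsig.differential import signed_log_t

from conftest import make_table


def three_state_samples(n=3):
    out = {}
    for st_ in ("parental", "persistent", "resistant"):
        for r in range(n):
            out[f"{st_[:3]}{r}"] = ("L1", st_, r + 1)
    return out


# ---------------------------------------------------------------- normalize

def test_median_center_columns():
    t = make_table({"P1_S1": [1, 5, 1, 2], "P2_S1": [2, 6, 3, 4], "P3_S1": [3, 7, 5, 6]})
    out = normalize_median_center(t)
    assert np.allclose(out.values["a0"], [-1, 0, 1])
    assert np.allclose(out.values.median(axis=0), 0)
    again = normalize_median_center(out)
    assert np.allclose(again.values, out.values)  # idempotent


def test_median_center_random_postcondition():
    rng = np.random.default_rng(3)
    vals = rng.normal(size=(50, 4))
    t = make_table({f"P{i}_S1": vals[i] for i in range(50)})
    out = normalize_median_center(t)
    assert np.nanmax(np.abs(out.values.median(axis=0))) < 1e-12


def test_median_center_needs_two_values():
    t = make_table({"P1_S1": [1.0, np.nan, 2.0, 3.0], "P2_S1": [np.nan, np.nan, 1.0, 1.0]})
    with pytest.raises(DataError, match="<2 present"):
        normalize_median_center(t)


# ---------------------------------------------------------------- t-test

def test_pooled_t_closed_form(two_group_contrast):
    t = make_table({"P1_S1": [1, 2, 3, 4, 5, 6]},
                   samples={**{f"a{r}": ("L1", "parental", r + 1) for r in range(3)},
                            **{f"b{r}": ("L1", "resistant", r + 1) for r in range(3)}})
    res = feature_ttest(t, two_group_contrast)
    row = res.iloc[0]
    assert row["log2fc"] == pytest.approx(3.0)
    assert row["stat"] == pytest.approx(-3.6742346141747673, abs=1e-12)
    assert row["p"] == pytest.approx(0.021311641128756713, rel=1e-10)
    assert np.sign(row["s"]) == np.sign(row["log2fc"])


def test_identical_groups_null(two_group_contrast):
    t = make_table({"P1_S1": [1, 2, 3, 1, 2, 3]})
    res = feature_ttest(t, two_group_contrast)
    assert res.iloc[0]["stat"] == 0
    assert res.iloc[0]["p"] == 1
    assert res.iloc[0]["s"] == 0


def test_zero_variance_sentinel(two_group_contrast):
    t = make_table({"P1_S1": [1, 1, 1, 2, 2, 2]})
    res = feature_ttest(t, two_group_contrast)
    assert res.iloc[0]["p"] == 1e-300
    assert res.iloc[0]["flag"] == "zero_variance"
    assert res.iloc[0]["s"] == 300.0  # capped


def test_insufficient_replicates_flagged_not_dropped(two_group_contrast):
    t = make_table({"P1_S1": [1, np.nan, np.nan, 4, 5, 6], "P2_S1": [1, 2, 3, 4, 5, 6]})
    res = feature_ttest(t, two_group_contrast)
    assert len(res) == 2
    assert res.loc["P1_S1", "flag"] == "insufficient_replicates"
    assert np.isnan(res.loc["P1_S1", "p"])
    assert res.loc["P2_S1", "flag"] == ""


def test_bh_step_up_fixture(two_group_contrast):
    from statsmodels.stats.multitest import multipletests
    q = multipletests([0.01, 0.02, 0.03, 0.04], method="fdr_bh")[1]
    assert np.allclose(q, 0.04)


# ---------------------------------------------------------------- ANOVA

def test_anova_closed_form():
    t = make_table(
        {"P1_S1": [1, 2, 3, 2, 3, 4, 3, 4, 5]}, samples=three_state_samples()
    )
    groups = [("L1", "parental"), ("L1", "persistent"), ("L1", "resistant")]
    res = feature_anova(t, groups)
    assert res.iloc[0]["stat"] == pytest.approx(3.0, abs=1e-12)
    assert res.iloc[0]["p"] == pytest.approx(0.125, abs=1e-12)
    assert res.iloc[0]["log2fc"] == pytest.approx(1.0)  # persistent - parental


def test_anova_identical_groups():
    t = make_table({"P1_S1": [5, 6, 7] * 3}, samples=three_state_samples())
    groups = [("L1", "parental"), ("L1", "persistent"), ("L1", "resistant")]
    res = feature_anova(t, groups)
    assert res.iloc[0]["stat"] == 0
    assert res.iloc[0]["p"] == 1


def test_anova_requires_three_groups():
    t = make_table({"P1_S1": [1, 2, 3, 4]})
    with pytest.raises(DataError, match=">=3"):
        feature_anova(t, [("L1", "parental"), ("L1", "resistant")])


# ---------------------------------------------------------------- filter

def _filter_fixture():
    q = [0.1, 0.1, 0.3, 0.15, 0.19, 0.5]
    fold = [2.5, 1.5, 4.0, 2.0, 8.0, 1.1]
    df = pd.DataFrame(
        {
            "protein_id": [f"P{i}" for i in range(6)],
            "site_label": ["S1"] * 6,
            "log2fc": np.log2(fold),
            "stat": 1.0,
            "p": q,
            "q": q,
            "s": 1.0,
        },
        index=[f"P{i}_S1" for i in range(6)],
    )
    df.attrs["test"] = "student_t"
    return df


def test_filter_fixture_survivors():
    df = _filter_fixture()
    out = apply_filter(df, FilterSpec(max_q=0.2, min_abs_fold=2.0))
    assert set(out.index) == {"P0_S1", "P3_S1", "P4_S1"}
    assert out.attrs["n_survivors"] == 3


def test_filter_pass_all_and_empty():
    df = _filter_fixture()
    assert apply_filter(df, FilterSpec(max_q=1.0, min_abs_fold=1.0)).attrs["n_survivors"] == 6
    empty = df.iloc[:0]
    empty.attrs["test"] = "student_t"
    assert apply_filter(empty, FilterSpec(max_q=0.2, min_abs_fold=2.0)).empty


def test_filter_monotone_in_thresholds():
    rng = np.random.default_rng(5)
    df = _filter_fixture().copy()
    df["q"] = rng.random(6)
    df["log2fc"] = rng.normal(0, 2, 6)
    df.attrs["test"] = "student_t"
    prev = None
    for fold in (1.0, 1.5, 2.0, 3.0, 5.0):
        n = apply_filter(df, FilterSpec(max_q=0.5, min_abs_fold=fold)).attrs["n_survivors"]
        if prev is not None:
            assert n <= prev
        prev = n
    prev = None
    for q in (0.05, 0.1, 0.3, 0.6, 1.0):
        n = apply_filter(df, FilterSpec(max_q=q, min_abs_fold=1.5)).attrs["n_survivors"]
        if prev is not None:
            assert n >= prev
        prev = n


def test_filter_spec_validation():
    with pytest.raises(ValueError):
        FilterSpec(max_q=0.0)
    with pytest.raises(ValueError):
        FilterSpec(max_q=0.1, min_abs_fold=0.5)


# ---------------------------------------------------------------- summarize

def test_protein_summarize_median_of_centered():
    t = make_table(
        {"P1_a": [1, 2, 3, 4], "P1_b": [0, 0, 4, 4]},
        proteins={"P1_a": "P1", "P1_b": "P1"},
        sites={"P1_a": "a", "P1_b": "b"},
    )
    out = protein_summarize(t)
    assert np.allclose(out.values.loc["P1"], [-1.75, -1.25, 1.25, 1.75])


def test_protein_summarize_single_peptide_passthrough():
    t = make_table({"P1_a": [2, 4, 2, 4]}, proteins={"P1_a": "P1"}, sites={"P1_a": "a"})
    out = protein_summarize(t)
    assert np.allclose(out.values.loc["P1"], [-1, 1, -1, 1])


def test_protein_summarize_duplication_invariant():
    rng = np.random.default_rng(8)
    vals = rng.normal(size=(6, 4))
    base = {f"P{i % 2}_s{i}": vals[i] for i in range(6)}
    prot = {k: k.split("_")[0] for k in base}
    t1 = protein_summarize(make_table(base, proteins=prot, sites={k: k.split("_")[1] for k in base}))
    dup = dict(base)
    dup.update({k + "d": v for k, v in base.items()})
    protd = {k: k.replace("d", "").split("_")[0] for k in dup}
    t2 = protein_summarize(
        make_table(dup, proteins=protd, sites={k: k.split("_")[1] for k in dup})
    )
    assert np.allclose(t1.values, t2.values.loc[t1.values.index])


# ---------------------------------------------------------------- collapse

def test_collapse_largest_absolute_sum():
    df = pd.DataFrame(
        {"protein_id": ["P1", "P1", "P2"], "site_label": ["S1", "S2", "S1"],
         "S": [5.0, -6.0, 2.0]},
        index=["P1_S1", "P1_S2", "P2_S1"],
    )
    out = collapse_to_protein(df)
    assert out.loc["P1", "score"] == -6.0
    assert out.loc["P1", "site_label"] == "S2"
    assert out.loc["P2", "score"] == 2.0


def test_collapse_tie_prefers_positive():
    df = pd.DataFrame(
        {"protein_id": ["P1", "P1"], "site_label": ["S9", "S1"], "S": [-4.0, 4.0]},
        index=["P1_S9", "P1_S1"],
    )
    out = collapse_to_protein(df)
    assert out.loc["P1", "score"] == 4.0
    assert bool(out.loc["P1", "tie_flag"])


# ---------------------------------------------------------------- rankings

def test_signed_t_order():
    df = pd.DataFrame(
        {"log2fc": [1.0, -1.0, 1.0], "stat": [-3.0, 2.0, -1.0]},
        index=["f1", "f2", "f3"],
    )
    r = signed_t_order(df)
    assert r.ids == ["f1", "f3", "f2"]


def test_signed_t_order_matches_brute_force():
    rng = np.random.default_rng(12)
    df = pd.DataFrame(
        {"log2fc": rng.normal(size=1000), "stat": rng.normal(size=1000)},
        index=[f"f{i}" for i in range(1000)],
    )
    r = signed_t_order(df)
    score = np.sign(df["log2fc"]) * df["stat"].abs()
    oracle = [k for k, _ in sorted(score.items(), key=lambda kv: (-kv[1], kv[0]))]
    assert r.ids == oracle


def test_sum_fold_change_signature():
    def mk(fcs):
        df = pd.DataFrame({"log2fc": fcs}, index=["f1", "f2", "f3"])
        return df

    a = mk([1.0, -1.0, 3.0])
    b = mk([2.0, 0.5, -3.0])
    r = sum_fold_change_signature([a, b])
    assert r.ids == ["f1", "f3", "f2"]
    assert np.allclose(r.scores, [3.0, 0.0, -0.5])
    single = sum_fold_change_signature([a])
    assert single.ids == ["f3", "f1", "f2"]
    doubled = sum_fold_change_signature([a, a])
    assert doubled.ids == single.ids
    assert np.allclose(doubled.scores, 2 * single.scores)


def test_signed_log_t_score_modes():
    s = signed_log_t(np.array([1.0]), np.array([0.01]), np.array([-3.0]))
    assert s[0] == pytest.approx(2.0)
    s = signed_log_t(np.array([-1.0]), np.array([0.001]), np.array([3.0]))
    assert s[0] == pytest.approx(-3.0)
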