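"""Permutation-KS and GSEA-style enrichment: statistics and calibration."""

import numpy as np
import pandas as pd
import pytest

from adaptsig import (
    Contrast,
    GeneSetCollection,
    feature_ttest,
    gsea_es_nes,
    kinase_enrichment,
    ks_permutation_test,
    rank_features,
    specificity_filter,
)
from adaptsig.core import DataError


def _ranked(n, seed=0):
    rng = np.random.default_rng(seed)
    return rank_features({f"g{i:03d}": float(x) for i, x in enumerate(rng.normal(size=n))})


def _ranked_ordered(n):
    # g000 highest score, g(n-1) lowest
    return rank_features({f"g{i:03d}": float(n - i) for i in range(n)})


def test_ks_d_top_block():
    ranked = _ranked_ordered(20)
    top5 = {f"g{i:03d}" for i in range(5)}
    res = ks_permutation_test(ranked, top5, B=10000, seed=1)
    assert res.stat == pytest.approx(0.75)
    assert res.p <= 0.01
    assert set(res.leading_edge) == top5


def test_ks_uniformly_spread_set_not_enriched():
    ranked = _ranked_ordered(20)
    spread = {f"g{i:03d}" for i in (3, 7, 11, 15, 19)}  # positions 4,8,12,16,20
    res = ks_permutation_test(ranked, spread, B=999, seed=2)
    assert res.stat == pytest.approx(0.0)
    assert res.p > 0.5


def test_ks_set_equals_universe_degenerate():
    ranked = _ranked_ordered(10)
    res = ks_permutation_test(ranked, set(ranked.ids), B=99, seed=0)
    assert res.stat == 0.0 and res.p == 1.0
    assert res.flag == "set_equals_universe"


def test_ks_empty_intersection_error():
    with pytest.raises(DataError, match="intersect"):
        ks_permutation_test(_ranked_ordered(10), {"zz"}, B=99, seed=0)


def test_ks_p_never_below_one_over_b_plus_one():
    ranked = _ranked_ordered(50)
    res = ks_permutation_test(ranked, {f"g{i:03d}" for i in range(10)}, B=199, seed=3)
    assert res.p >= 1 / 200


def test_ks_bottom_side():
    ranked = _ranked_ordered(20)
    bottom = {f"g{i:03d}" for i in range(15, 20)}
    res = ks_permutation_test(ranked, bottom, B=999, seed=4, side="bottom")
    assert res.stat == pytest.approx(0.75)
    assert res.p <= 0.05


def running_sum_oracle(ranked, members, weight):
    """Literal walk over the full list; returns the signed extremum ES."""
    member_set = set(members)
    absw = np.abs(ranked.scores) ** weight if weight > 0 else np.ones(len(ranked))
    tot = sum(absw[i] for i, g in enumerate(ranked.ids) if g in member_set)
    n_miss = len(ranked) - len(member_set)
    run, best = 0.0, 0.0
    for i, g in enumerate(ranked.ids):
        if g in member_set:
            run += absw[i] / tot
        else:
            run -= 1.0 / n_miss
        if abs(run) > abs(best) or (abs(run) == abs(best) and run > best):
            best = run
    return best


@pytest.mark.parametrize("weight", [0.0, 1.0])
def test_gsea_es_matches_running_sum_oracle(weight):
    rng = np.random.default_rng(6)
    for trial in range(50):
        n = int(rng.integers(20, 80))
        m = int(rng.integers(3, 8))
        ranked = _ranked(n, seed=100 + trial)
        members = sorted(rng.choice(ranked.ids, size=m, replace=False))
        sets = GeneSetCollection(sets={"s": tuple(members)})
        es = gsea_es_nes(ranked, sets, B=99, seed=trial, weight=weight).loc["s", "es"]
        assert es == pytest.approx(running_sum_oracle(ranked, members, weight), abs=1e-12)


def test_unweighted_es_and_ks_d_agree_on_top_enrichment():
    # both walks peak at the end of a top-block; the KS background ECDF is
    # uniform over N while the ES miss-step is 1/(N-m), so the statistics
    # differ in general but must agree in ordering for a planted top block
    ranked = _ranked_ordered(40)
    top = {f"g{i:03d}" for i in range(8)}
    d = ks_permutation_test(ranked, top, B=199, seed=0).stat
    es = gsea_es_nes(ranked, GeneSetCollection(sets={"s": tuple(sorted(top))}),
                     B=199, seed=0, weight=0.0).loc["s", "es"]
    assert d == pytest.approx(1 - 8 / 40)
    assert es == pytest.approx(1.0)
    assert es >= d > 0


def test_gsea_bottom_set_negative_nes():
    ranked = _ranked_ordered(50)
    bottom = tuple(f"g{i:03d}" for i in range(42, 50))
    res = gsea_es_nes(ranked, GeneSetCollection(sets={"b": bottom}), B=499, seed=1)
    assert res.loc["b", "es"] < 0
    assert res.loc["b", "nes"] < 0
    assert set(res.loc["b", "leading_edge"]) == set(bottom)


def test_gsea_es_sign_flips_on_reversal():
    ranked = _ranked(60, seed=9)
    members = tuple(ranked.ids[:6])
    sets = GeneSetCollection(sets={"s": members})
    es = gsea_es_nes(ranked, sets, B=99, seed=0).loc["s", "es"]
    es_rev = gsea_es_nes(ranked.reversed(), sets, B=99, seed=0).loc["s", "es"]
    assert es_rev == pytest.approx(-es, abs=1e-12)


def test_gsea_small_set_skipped():
    ranked = _ranked_ordered(20)
    res = gsea_es_nes(ranked, GeneSetCollection(sets={"tiny": ("g001", "g002")}), B=99, seed=0)
    assert res.loc["tiny", "flag"] == "too_small"
    assert np.isnan(res.loc["tiny", "p"])


def _fake_results(entries):
    df = pd.DataFrame(entries).set_index("set_name")
    df["p"] = df["q"] / 2
    return df


def test_specificity_filter_rules():
    case1 = _fake_results([{"set_name": "A", "q": 0.05, "nes": 2.0},
                           {"set_name": "B", "q": 0.05, "nes": 1.5}])
    case2 = _fake_results([{"set_name": "A", "q": 0.08, "nes": 1.8},
                           {"set_name": "B", "q": 0.15, "nes": 1.2}])
    control = _fake_results([{"set_name": "A", "q": 0.5, "nes": 0.2},
                             {"set_name": "B", "q": 0.5, "nes": 0.1}])
    out = specificity_filter([case1, case2], control, q_case=0.1, q_control=0.2)
    assert list(out.index) == ["A"]  # B fails the all-cases rule
    assert out.loc["A", "sum_nes"] == pytest.approx(3.8)


def test_specificity_filter_missing_set_excluded():
    case1 = _fake_results([{"set_name": "A", "q": 0.05, "nes": 2.0}])
    case2 = _fake_results([{"set_name": "A", "q": 0.05, "nes": 2.0}])
    control = _fake_results([{"set_name": "Z", "q": 0.5, "nes": 0.0}])
    out = specificity_filter([case1, case2], control)
    assert "A" in out.attrs["excluded"]


def test_kinase_enrichment_planted_substrates(small_simulation):
    cfg, (table, sets, truth) = small_simulation
    c = Contrast("res1", ("RTK1", "parental"), ("RTK1", "resistant"))
    diff = feature_ttest(table, c)
    sub = sets.subset([n for n in sets.names() if n.startswith("substrates_")])
    res = kinase_enrichment(diff, sub, B=1000, seed=7)
    assert res.loc["substrates_shared_kinase", "nes"] > 0
    assert res.loc["substrates_shared_kinase", "q"] < 0.2
    assert bool(res.loc["substrates_shared_kinase", "passes"])
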