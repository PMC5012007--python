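"""Signature correlation matrices and hierarchical clustering."""

import numpy as np
import pandas as pd
import pytest

from adaptsig import (
    cut_clusters,
    hierarchical_cluster,
    linkage_to_newick,
    pairwise_signature_correlation,
)
from adaptsig.core import DataError


def _series(vals, ids=None):
    ids = ids or [f"g{i}" for i in range(len(vals))]
    return pd.Series(np.asarray(vals, dtype=float), index=ids)


def test_pearson_fixtures():
    v = _series([1, 2, 3, 4])
    sm = pairwise_signature_correlation({"a": v, "b": v.copy(), "c": -v, "d": _series([1, 3, 2, 4])})
    assert sm.correlations.loc["a", "b"] == pytest.approx(1.0)
    assert sm.correlations.loc["a", "c"] == pytest.approx(-1.0)
    assert sm.correlations.loc["a", "d"] == pytest.approx(0.8)
    assert sm.n_overlap.loc["a", "d"] == 4


def test_constant_vector_flagged_not_zero():
    sm = pairwise_signature_correlation({"a": _series([1, 2, 3]), "b": _series([5, 5, 5])})
    assert np.isnan(sm.correlations.loc["a", "b"])
    with pytest.raises(DataError, match="missing"):
        hierarchical_cluster(sm)


def test_min_overlap_enforced():
    with pytest.raises(DataError, match="share only"):
        pairwise_signature_correlation(
            {"a": _series([1, 2], ids=["x", "y"]), "b": _series([1, 2], ids=["z", "w"])}
        )


def test_correlation_invariant_to_affine_transform():
    rng = np.random.default_rng(1)
    sigs = {f"s{i}": _series(rng.normal(size=30)) for i in range(4)}
    r1 = pairwise_signature_correlation(sigs).correlations
    r2 = pairwise_signature_correlation(
        {k: 3.5 * v + 7.0 for k, v in sigs.items()}
    ).correlations
    assert np.allclose(r1, r2)


def _block_signatures(seed=3, n_ids=200):
    rng = np.random.default_rng(seed)
    base1 = rng.normal(size=n_ids)
    base2 = rng.normal(size=n_ids)
    sigs = {}
    for i in range(3):
        sigs[f"blockA_{i}"] = _series(base1 + 0.3 * rng.normal(size=n_ids))
    for i in range(3):
        sigs[f"blockB_{i}"] = _series(base2 + 0.3 * rng.normal(size=n_ids))
    return sigs


def test_two_planted_blocks_recovered():
    sm = hierarchical_cluster(pairwise_signature_correlation(_block_signatures()))
    labels = cut_clusters(sm, k=2)
    block_a = {labels[n] for n in labels if n.startswith("blockA")}
    block_b = {labels[n] for n in labels if n.startswith("blockB")}
    assert len(block_a) == 1 and len(block_b) == 1 and block_a != block_b


def test_two_signatures_trivial_merge():
    rng = np.random.default_rng(0)
    sm = hierarchical_cluster(
        pairwise_signature_correlation(
            {"a": _series(rng.normal(size=10)), "b": _series(rng.normal(size=10))}
        )
    )
    assert sm.linkage.shape == (1, 4)
    assert sorted(sm.leaf_order) == ["a", "b"]


def upgma_oracle(dist):
    """Brute-force size-weighted average-linkage agglomeration."""
    n = dist.shape[0]
    clusters = {i: [i] for i in range(n)}
    d = {(i, j): dist[i, j] for i in range(n) for j in range(i + 1, n)}
    heights = []
    nxt = n
    while len(clusters) > 1:
        (i, j), h = min(d.items(), key=lambda kv: kv[1])
        heights.append(h)
        merged = clusters[i] + clusters[j]
        del clusters[i], clusters[j]
        d = {k: v for k, v in d.items() if i not in k and j not in k}
        for k in list(clusters):
            dk = np.mean([dist[a, b] for a in merged for b in clusters[k]])
            d[(min(k, nxt), max(k, nxt))] = dk
        clusters[nxt] = merged
        nxt += 1
    return heights


def test_average_linkage_heights_match_oracle():
    rng = np.random.default_rng(5)
    for trial in range(3):
        n = 5 + trial
        x = rng.normal(size=(n, 40))
        sigs = {f"s{i}": _series(x[i]) for i in range(n)}
        sm = hierarchical_cluster(pairwise_signature_correlation(sigs))
        dist = 1.0 - sm.correlations.to_numpy()
        np.fill_diagonal(dist, 0.0)
        assert np.allclose(sorted(sm.linkage[:, 2]), sorted(upgma_oracle(dist)), atol=1e-10)


def test_clustering_invariant_to_input_order():
    sigs = _block_signatures(seed=7)
    sm1 = hierarchical_cluster(pairwise_signature_correlation(sigs))
    rev = dict(reversed(list(sigs.items())))
    sm2 = hierarchical_cluster(pairwise_signature_correlation(rev))
    part1 = frozenset(
        frozenset(n for n, l in cut_clusters(sm1, 2).items() if l == c) for c in (1, 2)
    )
    part2 = frozenset(
        frozenset(n for n, l in cut_clusters(sm2, 2).items() if l == c) for c in (1, 2)
    )
    assert part1 == part2


def test_newick_rendering():
    rng = np.random.default_rng(2)
    sigs = {f"s{i}": _series(rng.normal(size=20)) for i in range(4)}
    sm = hierarchical_cluster(pairwise_signature_correlation(sigs))
    nwk = linkage_to_newick(sm.linkage, sm.names)
    assert nwk.endswith(";")
    for name in sigs:
        assert name in nwk
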