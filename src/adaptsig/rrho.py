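"""Rank–rank hypergeometric overlap (RRHO) maps.

Given two ranked lists over the same identifier universe, every pair of
rank thresholds (i, j) asks: how surprising is the size of the overlap
between the top-i of list A and the top-j of list B?  The answer is the
hypergeometric tail P(X ≥ k), displayed as a −log10 p grid whose maximum
locates the strongest agreement region between the two rankings.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .core import DataError, RankedList

__all__ = ["RRHOMap", "hypergeometric_tail", "rrho_map"]


def hypergeometric_tail(N: int, K: int, n: int, k: int) -> float:
    """Upper tail P(X ≥ k) for X ~ Hypergeometric(N, K, n), log-space safe.

    N = universe size, K = successes in universe, n = draws, k = observed
    successes.  k = 0 returns exactly 1.
    """
    if not (0 <= k <= min(K, n) <= N) or n > N or K > N:
        raise DataError(f"inconsistent hypergeometric parameters N={N} K={K} n={n} k={k}")
    if k == 0:
        return 1.0
    return float(np.exp(stats.hypergeom.logsf(k - 1, N, K, n)))


@dataclass
class RRHOMap:
    """Grid of −log10 overlap p-values over rank-threshold pairs.

    ``values[i, j]`` corresponds to thresholds ``thresholds_a[i]`` of the
    first list and ``thresholds_b[j]`` of the second.  In signed mode,
    depletion (k below expectation) is reported as −(−log10 P(X ≤ k)),
    i.e. negative values.
    """

    thresholds_a: np.ndarray
    thresholds_b: np.ndarray
    values: np.ndarray  # -log10 p, possibly signed
    overlap: np.ndarray  # k per cell
    N: int
    correction: str = "none"
    signed: bool = False
    n_discarded: int = 0

    def __post_init__(self) -> None:
        if self.values.shape != (len(self.thresholds_a), len(self.thresholds_b)):
            raise DataError("value matrix does not match threshold grid")
        if (self.thresholds_a > self.N).any() or (self.thresholds_b > self.N).any():
            raise DataError("threshold exceeds universe size")

    @property
    def max_value(self) -> float:
        return float(self.values.max())

    @property
    def max_location(self) -> tuple[int, int]:
        """(threshold_a, threshold_b) of the map maximum."""
        i, j = np.unravel_index(int(np.argmax(self.values)), self.values.shape)
        return int(self.thresholds_a[i]), int(self.thresholds_b[j])

    def summary(self) -> dict:
        return {
            "N": self.N,
            "max_neglog10_p": self.max_value,
            "max_location": list(self.max_location),
            "correction": self.correction,
            "n_discarded": self.n_discarded,
        }


def rrho_map(
    list_a: RankedList,
    list_b: RankedList,
    step: int | None = None,
    correction: str = "none",
    signed: bool = False,
) -> RRHOMap:
    """Compute the RRHO map of two ranked lists.

    The universe is the intersection of the two lists' identifiers
    (discarded identifiers are counted); thresholds run step, 2·step, …, N
    with the default step max(1, ⌊N/100⌋).  ``correction`` applies BH or
    BY across all cells of the (enrichment) map.
    """
    if correction not in ("none", "BH", "BY"):
        raise ValueError(f"unknown correction {correction!r}")
    common = set(list_a.ids) & set(list_b.ids)
    if not common:
        raise DataError("ranked lists share no identifiers")
    n_discarded = (len(list_a) - len(common)) + (len(list_b) - len(common))
    ids_a = [i for i in list_a.ids if i in common]
    ids_b = [i for i in list_b.ids if i in common]
    N = len(common)
    if step is None:
        step = max(1, N // 100)
    if not (1 <= step <= N):
        raise DataError(f"step {step} out of range for N={N}")

    thresholds = np.arange(step, N + 1, step)
    if thresholds[-1] != N:
        thresholds = np.append(thresholds, N)
    T = len(thresholds)

    rank_b = {ident: r for r, ident in enumerate(ids_b, start=1)}
    ra = np.arange(1, N + 1)
    rb = np.array([rank_b[i] for i in ids_a])
    # bin each identifier's (rankA, rankB) into the threshold grid, then
    # 2-D cumulative count gives k(i, j) = |top-i of A ∩ top-j of B|
    bins_a = np.searchsorted(thresholds, ra)
    bins_b = np.searchsorted(thresholds, rb)
    hist = np.zeros((T, T), dtype=np.int64)
    np.add.at(hist, (bins_a, bins_b), 1)
    k = hist.cumsum(axis=0).cumsum(axis=1)

    logsf = np.empty((T, T))
    logcdf = np.empty((T, T)) if signed else None
    for i, ti in enumerate(thresholds):
        # vectorize over j for fixed K=ti
        kk = k[i]
        with np.errstate(divide="ignore"):
            logsf[i] = stats.hypergeom.logsf(kk - 1, N, ti, thresholds)
            if signed:
                logcdf[i] = stats.hypergeom.logcdf(kk, N, ti, thresholds)
    logsf[k == 0] = 0.0  # P(X >= 0) = 1 exactly

    log10 = np.log(10.0)
    p_enr = np.exp(logsf)
    if correction != "none":
        method = "fdr_bh" if correction == "BH" else "fdr_by"
        p_flat = np.minimum(p_enr.ravel(), 1.0)
        p_enr = multipletests(p_flat, method=method)[1].reshape(p_enr.shape)
        neglog = -np.log10(np.maximum(p_enr, 1e-320))
    else:
        neglog = -logsf / log10

    if signed:
        depleted = np.exp(logcdf) < p_enr
        values = np.where(depleted, logcdf / log10, neglog)
    else:
        values = neglog

    return RRHOMap(
        thresholds_a=thresholds,
        thresholds_b=thresholds,
        values=values,
        overlap=k,
        N=N,
        correction=correction,
        signed=signed,
        n_discarded=n_discarded,
    )
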