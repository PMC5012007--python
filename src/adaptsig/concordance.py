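"""Direction-of-change concordance between two contrasts.

Significantly altered features from two contrasts (e.g. resistant-vs-
parental in two cell lines) are cross-tabulated by the sign of their fold
change, and the association of directions is assessed with Fisher's exact
test — concordant adaptation programs give a heavily diagonal 2×2 table.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core import DataError

__all__ = ["DirectionTable", "build_direction_table", "fisher_exact_2x2"]


@dataclass
class DirectionTable:
    """2×2 counts: rows = up/down in contrast A, cols = up/down in B."""

    counts: np.ndarray  # shape (2, 2), int
    n_excluded_zero: int = 0
    policy: str = "either"
    alpha: float = 0.05

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.shape != (2, 2):
            raise DataError("direction table must be 2x2")
        if (self.counts < 0).any():
            raise DataError("negative counts")
        if self.counts.sum() < 1:
            raise DataError("direction table is empty")

    @property
    def concordant_fraction(self) -> float:
        return float(np.trace(self.counts) / self.counts.sum())

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.counts, index=["A_up", "A_down"], columns=["B_up", "B_down"]
        )


def build_direction_table(
    diff_a: pd.DataFrame,
    diff_b: pd.DataFrame,
    sig_policy: str = "either",
    alpha: float = 0.2,
    use_q: bool = True,
) -> DirectionTable:
    """Cross-tabulate fold-change directions of significant shared features.

    ``sig_policy="either"`` keeps features significant in at least one
    contrast, ``"both"`` requires both.  The default alpha matches the
    phospho-profile FDR threshold (q < 0.2).  Features with a zero fold change
    in either contrast are excluded and counted.
    """
    if sig_policy not in ("either", "both"):
        raise ValueError(f"unknown policy {sig_policy!r}")
    col = "q" if use_q else "p"
    shared = diff_a.index.intersection(diff_b.index)
    if len(shared) == 0:
        raise DataError("no shared features between contrasts")
    a = diff_a.loc[shared]
    b = diff_b.loc[shared]
    sig_a = a[col] < alpha
    sig_b = b[col] < alpha
    sig = (sig_a | sig_b) if sig_policy == "either" else (sig_a & sig_b)
    sig = sig.fillna(False)
    fa = a["log2fc"]
    fb = b["log2fc"]
    nonzero = (fa != 0) & (fb != 0) & fa.notna() & fb.notna()
    keep = sig & nonzero
    n_excl = int((sig & ~nonzero).sum())
    if keep.sum() == 0:
        raise DataError("no qualifying features for direction table")
    up_a = fa[keep] > 0
    up_b = fb[keep] > 0
    counts = np.array(
        [
            [int((up_a & up_b).sum()), int((up_a & ~up_b).sum())],
            [int((~up_a & up_b).sum()), int((~up_a & ~up_b).sum())],
        ]
    )
    return DirectionTable(counts=counts, n_excluded_zero=n_excl, policy=sig_policy, alpha=alpha)


def fisher_exact_2x2(table: DirectionTable | np.ndarray, alternative: str = "two-sided") -> float:
    """Fisher's exact p for a 2×2 table.

    Two-sided p sums hypergeometric probabilities (at fixed margins) of
    tables no more probable than the observed one (minimum-likelihood
    convention).
    """
    counts = table.counts if isinstance(table, DirectionTable) else np.asarray(table)
    if counts.sum() < 1:
        raise DataError("all-zero table")
    return float(stats.fisher_exact(counts, alternative=alternative)[1])
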