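"""Pairwise signature correlation and hierarchical clustering.

Signatures are fold-change vectors over a shared identifier universe
(e.g. per-cell-line resistant-vs-parental log2 fold changes, published
phenotype-switch signatures, negative controls).  Pearson r is computed on
pairwise-complete identifiers; agglomerative clustering uses the distance
1 − r, so anti-correlating control signatures end up maximally distant.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .core import DataError

__all__ = [
    "SignatureMatrix",
    "pairwise_signature_correlation",
    "hierarchical_cluster",
    "cut_clusters",
    "linkage_to_newick",
]


@dataclass
class SignatureMatrix:
    correlations: pd.DataFrame  # symmetric, unit diagonal, NaN where undefined
    n_overlap: pd.DataFrame
    linkage: np.ndarray | None = None
    leaf_order: list[str] | None = None

    @property
    def names(self) -> list[str]:
        return list(self.correlations.index)


def pairwise_signature_correlation(
    signatures: Mapping[str, pd.Series], min_overlap: int = 3
) -> SignatureMatrix:
    """Pearson r for every signature pair on pairwise-complete identifiers.

    A pair sharing fewer than ``min_overlap`` identifiers is an error; a
    constant vector within a pair's overlap leaves r as NaN (flagged
    missing, never coerced to 0).
    """
    names = list(signatures)
    if len(names) < 2:
        raise DataError("need >=2 signatures")
    r = pd.DataFrame(np.eye(len(names)), index=names, columns=names)
    n = pd.DataFrame(0, index=names, columns=names, dtype=int)
    for i, a in enumerate(names):
        sa = signatures[a].dropna()
        n.loc[a, a] = len(sa)
        for b in names[i + 1 :]:
            sb = signatures[b].dropna()
            common = sa.index.intersection(sb.index)
            if len(common) < min_overlap:
                raise DataError(
                    f"signatures {a!r} and {b!r} share only {len(common)} identifiers"
                )
            x = sa.loc[common].to_numpy(dtype=float)
            y = sb.loc[common].to_numpy(dtype=float)
            if np.ptp(x) == 0 or np.ptp(y) == 0:
                rho = np.nan  # undefined for constant vectors
            else:
                rho = float(np.corrcoef(x, y)[0, 1])
            r.loc[a, b] = r.loc[b, a] = rho
            n.loc[a, b] = n.loc[b, a] = len(common)
    return SignatureMatrix(correlations=r, n_overlap=n)


def hierarchical_cluster(matrix: SignatureMatrix, linkage_rule: str = "average") -> SignatureMatrix:
    """Agglomerative clustering on the distance 1 − r.

    Returns a new :class:`SignatureMatrix` carrying the scipy linkage and
    the dendrogram leaf order.  Missing correlations are an error.
    """
    if linkage_rule not in ("average", "complete"):
        raise ValueError(f"unknown linkage rule {linkage_rule!r}")
    r = matrix.correlations
    if r.isna().any().any():
        raise DataError("correlation matrix has missing entries; cannot cluster")
    dist = 1.0 - r.to_numpy()
    np.fill_diagonal(dist, 0.0)
    condensed = squareform(dist, checks=False)
    Z = hierarchy.linkage(condensed, method=linkage_rule)
    order = [matrix.names[i] for i in hierarchy.leaves_list(Z)]
    return SignatureMatrix(
        correlations=matrix.correlations,
        n_overlap=matrix.n_overlap,
        linkage=Z,
        leaf_order=order,
    )


def cut_clusters(matrix: SignatureMatrix, k: int) -> dict[str, int]:
    """Flat cluster labels at k clusters."""
    if matrix.linkage is None:
        raise DataError("run hierarchical_cluster first")
    labels = hierarchy.fcluster(matrix.linkage, t=k, criterion="maxclust")
    return dict(zip(matrix.names, (int(x) for x in labels)))


def linkage_to_newick(Z: np.ndarray, labels: list[str]) -> str:
    """Render a scipy linkage matrix as a newick string with branch lengths."""
    tree = hierarchy.to_tree(Z)

    def rec(node, parent_height: float) -> str:
        length = parent_height - (0.0 if node.is_leaf() else node.dist)
        if node.is_leaf():
            return f"{labels[node.id]}:{parent_height:.6g}"
        left = rec(node.get_left(), node.dist)
        right = rec(node.get_right(), node.dist)
        return f"({left},{right}):{length:.6g}"

    return f"({rec(tree.get_left(), tree.dist)},{rec(tree.get_right(), tree.dist)});"
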