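"""The four community dissimilarity metrics: Jaccard, Bray-Curtis, and the
two UniFrac variants (weighted UniFrac in its normalized form, so that all
four metrics live on [0, 1]).

UniFrac computations are delegated to scikit-bio; pairwise helpers exist for
single community pairs and :func:`distance_matrix` builds the full
host-by-host matrix used by the detection tests.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.spatial.distance import braycurtis as _braycurtis
from skbio import DistanceMatrix, TreeNode
from skbio.diversity import beta_diversity

__all__ = [
    "jaccard",
    "bray_curtis",
    "unifrac_unweighted",
    "unifrac_weighted",
    "distance_matrix",
    "METRICS",
    "read_distance_matrix",
    "write_distance_matrix",
]

#: metric name -> whether a microbial tree is required
METRICS = {
    "jaccard": False,
    "braycurtis": False,
    "uunifrac": True,
    "wunifrac": True,
}


def _check_pair(a: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("communities must have equal length")
    if a.min() < 0 or b.min() < 0:
        raise ValueError("abundances must be nonnegative")
    if a.sum() == 0 and b.sum() == 0:
        raise ValueError("both communities are empty")
    return a, b


def jaccard(a, b) -> float:
    """1 - |shared taxa| / |union of taxa| on presence/absence."""
    a, b = _check_pair(a, b)
    pa, pb = a > 0, b > 0
    union = np.logical_or(pa, pb).sum()
    inter = np.logical_and(pa, pb).sum()
    return 1.0 - inter / union


def bray_curtis(a, b) -> float:
    """sum |a_i - b_i| / sum (a_i + b_i)."""
    a, b = _check_pair(a, b)
    return float(_braycurtis(a, b))


def _unifrac_pair(a, b, tree: TreeNode, taxa, weighted: bool) -> float:
    a, b = _check_pair(a, b)
    if weighted and (a.sum() == 0 or b.sum() == 0):
        raise ValueError("weighted UniFrac needs two non-empty communities")
    dm = beta_diversity(
        "weighted_unifrac" if weighted else "unweighted_unifrac",
        np.vstack([a, b]),
        ids=["a", "b"],
        taxa=list(taxa),
        tree=tree,
        **({"normalized": True} if weighted else {}),
    )
    return float(dm["a", "b"])


def unifrac_unweighted(a, b, tree: TreeNode, taxa) -> float:
    """Fraction of union-subtree branch length unique to either community.

    Depends on presence/absence only.
    """
    return _unifrac_pair(a, b, tree, taxa, weighted=False)


def unifrac_weighted(a, b, tree: TreeNode, taxa) -> float:
    """Normalized weighted UniFrac on relative abundances."""
    return _unifrac_pair(a, b, tree, taxa, weighted=True)


def distance_matrix(
    table: pd.DataFrame, metric: str, tree: TreeNode | None = None
) -> DistanceMatrix:
    """Pairwise dissimilarities between all hosts of a community table.

    ``metric`` is one of jaccard | braycurtis | uunifrac | wunifrac; the two
    UniFrac variants require the microbial ``tree`` (all table columns must
    be tips of it).
    """
    if metric not in METRICS:
        raise ValueError(f"unknown metric {metric!r}; choose from {sorted(METRICS)}")
    if METRICS[metric] and tree is None:
        raise ValueError(f"metric {metric!r} requires a microbial tree")
    counts = table.to_numpy(dtype=float)
    ids = [str(h) for h in table.index]
    if metric == "jaccard":
        return beta_diversity("jaccard", counts > 0, ids=ids)
    if metric == "braycurtis":
        return beta_diversity("braycurtis", counts, ids=ids)
    kind = "weighted_unifrac" if metric == "wunifrac" else "unweighted_unifrac"
    kwargs = {"normalized": True} if metric == "wunifrac" else {}
    return beta_diversity(
        kind,
        counts,
        ids=ids,
        taxa=[str(c) for c in table.columns],
        tree=tree,
        **kwargs,
    )


def read_distance_matrix(path) -> DistanceMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return DistanceMatrix(df.to_numpy(dtype=float), ids=[str(i) for i in df.index])


def write_distance_matrix(dm: DistanceMatrix, path) -> None:
    pd.DataFrame(dm.data, index=dm.ids, columns=dm.ids).to_csv(path, sep="\t")
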