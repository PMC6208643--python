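"""Phylosymbiosis detection: the Mantel approach, the dendrogram approach
(UPGMA + normalized Robinson-Foulds with permutation nulls), and the
host-trait Mantel sanity test.

Both tests are one-sided in the direction phylosymbiosis predicts: high
Pearson r between host phylogenetic distance and microbiota dissimilarity,
or low topological distance between the host tree and the microbiota
dendrogram.  Permutation p-values use the (count + 1) / (n_perm + 1)
convention, so p >= 1 / (n_perm + 1) always.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import pdist, squareform
from skbio import DistanceMatrix, TreeNode

__all__ = [
    "PhylosymbiosisResult",
    "mantel_test",
    "upgma",
    "clade_sets",
    "normalized_rf",
    "dendrogram_test",
    "trait_mantel",
    "cophenetic",
]


@dataclass(frozen=True)
class PhylosymbiosisResult:
    """Outcome of one detection test.

    ``statistic`` is Pearson's r (Mantel) or a normalized Robinson-Foulds
    distance (dendrogram approach).
    """

    method: str
    statistic: float
    p_value: float
    n_permutations: int
    null_model: str
    metric: str | None = None

    @property
    def significant(self) -> bool:
        # p <= alpha: for permutation p-values on the 1/(n_perm+1) grid this
        # is the exactly calibrated rejection rule
        return self.p_value <= 0.05


def _condensed(m: np.ndarray) -> np.ndarray:
    iu = np.triu_indices(m.shape[0], 1)
    return m[iu]


def mantel_test(
    d1: DistanceMatrix,
    d2: DistanceMatrix,
    n_perm: int = 999,
    seed: int | np.random.Generator | None = None,
    metric: str | None = None,
    method: str = "mantel",
) -> PhylosymbiosisResult:
    """One-sided Mantel test of the correlation between two distance matrices.

    Pearson's r is computed on the strictly-lower-triangle vectors; the null
    distribution jointly permutes rows and columns of ``d2``.  Significance
    is one-sided for positive correlation (the phylosymbiosis direction).
    """
    if set(d1.ids) != set(d2.ids):
        raise ValueError("distance matrices must share their label sets")
    if len(d1.ids) < 4:
        raise ValueError("Mantel test needs at least 4 labels")
    d2 = d2.filter(d1.ids)
    m1, m2 = d1.data, d2.data
    n = m1.shape[0]
    v1 = _condensed(m1)
    v2 = _condensed(m2)
    if v1.std() == 0 or v2.std() == 0:
        raise ValueError("Mantel test is degenerate: zero variance in a matrix")
    z1 = (v1 - v1.mean()) / v1.std()
    r_obs = float(np.mean(z1 * (v2 - v2.mean()) / v2.std()))

    rng = np.random.default_rng(seed)
    perms = np.array([rng.permutation(n) for _ in range(n_perm)])
    iu = np.triu_indices(n, 1)
    v2p = m2[perms[:, iu[0]], perms[:, iu[1]]]  # (n_perm, n_pairs)
    mu = v2p.mean(axis=1, keepdims=True)
    sd = v2p.std(axis=1, keepdims=True)
    r_null = ((v2p - mu) / sd * z1).mean(axis=1)
    # ties count as "as extreme"; the 1e-12 guard keeps permutations that
    # reproduce r_obs exactly (up to float error) in the tail
    p = (np.count_nonzero(r_null >= r_obs - 1e-12) + 1) / (n_perm + 1)
    return PhylosymbiosisResult(
        method=method,
        statistic=r_obs,
        p_value=float(p),
        n_permutations=n_perm,
        null_model="matrix_permutation",
        metric=metric,
    )


def upgma(d: DistanceMatrix) -> TreeNode:
    """Average-linkage (UPGMA) dendrogram of a distance matrix.

    Merge heights are half the average inter-cluster distance, so the result
    is ultrametric; on an ultrametric input (e.g. a cophenetic matrix) UPGMA
    reconstructs the generating topology exactly.
    """
    ids = list(d.ids)
    if len(ids) < 2:
        raise ValueError("UPGMA needs at least 2 labels")
    z = linkage(squareform(d.data, checks=False), method="average")
    nodes = [TreeNode(name=i) for i in ids]
    heights = [0.0] * len(ids)
    for a, b, dist, _ in z:
        left, right = nodes[int(a)], nodes[int(b)]
        h = dist / 2.0
        left.length = h - heights[int(a)]
        right.length = h - heights[int(b)]
        parent = TreeNode(children=[left, right])
        nodes.append(parent)
        heights.append(h)
    root = nodes[-1]
    root.length = None
    return root


def clade_sets(tree: TreeNode) -> set[frozenset[str]]:
    """Non-trivial rooted clades (tip-label sets) of a tree.

    Singletons and the full tip set are excluded; a rooted binary tree with
    n tips has n - 2 of them.
    """
    all_tips = frozenset(t.name for t in tree.tips())
    clades = set()
    for node in tree.non_tips(include_self=False):
        c = frozenset(t.name for t in node.tips())
        if 1 < len(c) < len(all_tips):
            clades.add(c)
    return clades


def normalized_rf(t1: TreeNode, t2: TreeNode) -> float:
    """Normalized Robinson-Foulds distance between two rooted trees.

    Size of the symmetric difference of the non-trivial clade sets, divided
    by 2(n - 2) — the maximum for rooted binary trees — so 0 means identical
    topologies and 1 means no shared clade.  Branch lengths are ignored.
    """
    tips1 = {t.name for t in t1.tips()}
    tips2 = {t.name for t in t2.tips()}
    if tips1 != tips2:
        raise ValueError("trees must share an identical leaf set")
    n = len(tips1)
    if n < 4:
        raise ValueError("normalized RF needs at least 4 leaves")
    c1, c2 = clade_sets(t1), clade_sets(t2)
    return len(c1 ^ c2) / (2 * (n - 2))


def _clade_masks(tree: TreeNode, index: dict[str, int]) -> list[np.ndarray]:
    """Non-trivial clades as arrays of tip indices (for fast remapping)."""
    n = len(index)
    masks = []
    for node in tree.non_tips(include_self=False):
        idx = [index[t.name] for t in node.tips()]
        if 1 < len(idx) < n:
            masks.append(np.asarray(idx))
    return masks


def _mask_int(bits: np.ndarray) -> int:
    return int(np.bitwise_or.reduce(1 << bits.astype(np.int64)))


def _random_yule_clade_masks(n: int, rng: np.random.Generator) -> list[int]:
    """Clade bitmasks of one random labelled Yule topology on n tips."""
    children: dict[int, tuple[int, int]] = {}
    active = [0]
    nxt = 1
    while len(active) < n:
        node = active.pop(int(rng.integers(len(active))))
        children[node] = (nxt, nxt + 1)
        active.extend((nxt, nxt + 1))
        nxt += 2
    labels = rng.permutation(n)
    mask: dict[int, int] = {
        tip: 1 << int(lab) for tip, lab in zip(active, labels)
    }
    out = []
    for node in sorted(children, reverse=True):  # children ids > parent id
        c1, c2 = children[node]
        mask[node] = mask[c1] | mask[c2]
        if node != 0:
            out.append(mask[node])
    return out


def dendrogram_test(
    host_tree: TreeNode,
    d: DistanceMatrix,
    n_perm: int = 999,
    null_model: str = "tip_shuffle",
    seed: int | np.random.Generator | None = None,
    metric: str | None = None,
) -> PhylosymbiosisResult:
    """Dendrogram approach: UPGMA the dissimilarities, compare topologies.

    The statistic is the normalized Robinson-Foulds distance between the
    host tree and the UPGMA dendrogram of ``d``.  The null distribution
    either reshuffles the host tree's tip labels (``tip_shuffle``) or draws
    fresh pure-birth topologies with the same tips (``random_trees``); the
    test is one-sided for small distances (topological congruence).
    """
    if null_model not in ("tip_shuffle", "random_trees"):
        raise ValueError(f"unknown null model {null_model!r}")
    host_tips = {t.name for t in host_tree.tips()}
    if host_tips != set(d.ids):
        raise ValueError("host tree tips and distance-matrix labels differ")
    n = len(d.ids)
    if n < 4:
        raise ValueError("dendrogram test needs at least 4 hosts")
    rng = np.random.default_rng(seed)
    index = {name: i for i, name in enumerate(sorted(host_tips))}
    dendro = upgma(d)
    dendro_masks = {
        _mask_int(m) for m in _clade_masks(dendro, index)
    }
    host_idx = _clade_masks(host_tree, index)
    norm = 2 * (n - 2)

    def rf_from_host_masks(masks: list[int]) -> float:
        matches = sum(1 for m in masks if m in dendro_masks)
        return (len(masks) + len(dendro_masks) - 2 * matches) / norm

    obs = rf_from_host_masks([_mask_int(m) for m in host_idx])
    hits = 0
    for _ in range(n_perm):
        if null_model == "tip_shuffle":
            perm = rng.permutation(n)
            null_masks = [_mask_int(perm[m]) for m in host_idx]
        else:
            null_masks = _random_yule_clade_masks(n, rng)
        if rf_from_host_masks(null_masks) <= obs:
            hits += 1
    p = (hits + 1) / (n_perm + 1)
    return PhylosymbiosisResult(
        method="dendrogram",
        statistic=obs,
        p_value=float(p),
        n_permutations=n_perm,
        null_model=null_model,
        metric=metric,
    )


def trait_mantel(
    host_traits: pd.DataFrame,
    d: DistanceMatrix,
    n_perm: int = 999,
    seed: int | np.random.Generator | None = None,
    metric: str | None = None,
) -> PhylosymbiosisResult:
    """Mantel test of host trait distance against microbiota dissimilarity.

    The sanity check of the filtering scenario: communities were filtered by
    this very trait, so its Euclidean distances should predict microbiota
    dissimilarity at least as well as phylogeny does.
    """
    x = host_traits.to_numpy(dtype=float)
    d1 = DistanceMatrix(
        squareform(pdist(x)), ids=[str(i) for i in host_traits.index]
    )
    return mantel_test(
        d1, d, n_perm=n_perm, seed=seed, metric=metric, method="trait_mantel"
    )


def cophenetic(tree: TreeNode) -> DistanceMatrix:
    """Patristic (path-length) distances between all tip pairs."""
    return tree.tip_tip_distances()
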