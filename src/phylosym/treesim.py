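"""Host and microbe phylogenies, trait evolution, and phylogenetic signal.

Trees are :class:`skbio.TreeNode` objects: rooted, binary, ultrametric, with
the root-to-tip height rescaled to 1 so that branch lengths are comparable
across simulations.  Continuous traits evolve by Brownian motion (BM), with
the amount of phylogenetic signal tuned through Pagel's delta transform of
node depths: delta < 1 pushes divergence toward the root (clade-structured
traits, strong signal), delta > 1 pushes it toward the tips (signal erased).
Realized signal is quantified with Blomberg's K, whose expectation is ~1
under plain BM on the untransformed tree.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skbio import TreeNode

__all__ = [
    "TraitEvolParams",
    "simulate_yule_tree",
    "delta_transform",
    "bm_covariance",
    "simulate_bm",
    "simulate_host_trait",
    "blomberg_k",
    "rescale_microbe_traits",
    "read_tree",
    "write_tree",
    "read_traits",
    "write_traits",
]

_HEIGHT_RTOL = 1e-9


@dataclass(frozen=True)
class TraitEvolParams:
    """Parameters of the delta-transformed Brownian trait model.

    delta : node-depth exponent (>0); 1 = plain BM.
    sigma2 : Brownian rate in trait-units^2 per unit tree height.  Every
        downstream statistic (correlations, min-max rescaled filters) is
        scale-invariant, so the default of 1 is not a tuning knob.
    n_traits : number of independent trait dimensions (1, 2 or 4).
    """

    delta: float = 1.0
    sigma2: float = 1.0
    n_traits: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.delta <= 0:
            raise ValueError(f"delta must be positive, got {self.delta}")
        if self.sigma2 < 0:
            raise ValueError(f"sigma2 must be nonnegative, got {self.sigma2}")
        if self.n_traits not in (1, 2, 4):
            raise ValueError(f"n_traits must be 1, 2 or 4, got {self.n_traits}")


@dataclass
class SignalEstimate:
    """Blomberg K per trait dimension; `mean_k` summarizes joint filters."""

    blomberg_k: np.ndarray = field(default_factory=lambda: np.array([]))

    @property
    def mean_k(self) -> float:
        return float(np.mean(self.blomberg_k))


def simulate_yule_tree(
    n_tips: int, seed: int | np.random.Generator, prefix: str = "t"
) -> TreeNode:
    """Simulate a pure-birth (Yule) tree and rescale its height to 1.

    Lineages split with unit rate (exponential waiting times, splitting
    lineage chosen uniformly); the birth rate is irrelevant after height
    rescaling.  Tips are labelled ``{prefix}1 .. {prefix}n``.
    """
    if n_tips < 2:
        raise ValueError(f"need at least 2 tips, got {n_tips}")
    rng = np.random.default_rng(seed)

    root = TreeNode()
    left, right = TreeNode(), TreeNode()
    root.extend([left, right])
    birth = {id(left): 0.0, id(right): 0.0}
    active = [left, right]
    t = 0.0
    while len(active) < n_tips:
        k = len(active)
        t += rng.exponential(1.0 / k)
        node = active.pop(int(rng.integers(k)))
        node.length = t - birth.pop(id(node))
        c1, c2 = TreeNode(), TreeNode()
        node.extend([c1, c2])
        birth[id(c1)] = birth[id(c2)] = t
        active.extend([c1, c2])
    # run the clock to the (unobserved) next split so the last split is not
    # flush with the tips
    t += rng.exponential(1.0 / n_tips)
    for i, node in enumerate(active):
        node.length = t - birth[id(node)]
        node.name = f"{prefix}{i + 1}"
    for node in root.preorder(include_self=False):
        node.length /= t
    root.length = None
    return root


def _check_unit_height(tree: TreeNode) -> None:
    depths = _tip_depths(tree)
    if not np.allclose(depths, 1.0, rtol=_HEIGHT_RTOL, atol=1e-9):
        raise ValueError(
            "tree must be ultrametric with height 1 "
            f"(tip depths span [{depths.min():.6g}, {depths.max():.6g}])"
        )


def _tip_depths(tree: TreeNode) -> np.ndarray:
    depth = {id(tree): 0.0}
    out = []
    for node in tree.preorder(include_self=False):
        d = depth[id(node.parent)] + (node.length or 0.0)
        depth[id(node)] = d
        if node.is_tip():
            out.append(d)
    return np.asarray(out)


def delta_transform(tree: TreeNode, delta: float) -> TreeNode:
    """Raise all node depths of a unit-height tree to the power ``delta``.

    Topology and tip labels are untouched; the result is again ultrametric
    with height 1 because d^delta maps [0, 1] onto [0, 1].
    """
    if delta <= 0:
        raise ValueError(f"delta must be positive, got {delta}")
    _check_unit_height(tree)
    out = tree.copy()
    depth = {id(out): 0.0}
    for node in out.preorder(include_self=False):
        d = depth[id(node.parent)] + (node.length or 0.0)
        depth[id(node)] = d
    for node in out.preorder(include_self=False):
        d = 1.0 if node.is_tip() else depth[id(node)]  # pin tips at exactly 1
        node.length = d**delta - depth[id(node.parent)] ** delta
    return out


def bm_covariance(tree: TreeNode) -> tuple[list[str], np.ndarray]:
    """Shared-path-length (phylogenetic) covariance matrix among tips.

    For an ultrametric tree C[i, j] is the depth of the MRCA of tips i and j,
    i.e. ``height - d(i, j) / 2``.
    """
    dm = tree.tip_tip_distances()
    tips = list(dm.ids)
    height = float(_tip_depths(tree).max())
    c = height - dm.data / 2.0
    return tips, c


def simulate_bm(tree: TreeNode, params: TraitEvolParams) -> pd.DataFrame:
    """Evolve ``params.n_traits`` independent Brownian traits on ``tree``.

    Tip values are multivariate normal with mean 0 (root state) and
    covariance sigma2 * C where C holds shared path lengths.  Returns a
    DataFrame indexed by tip label, one column per trait.
    """
    tips, c = bm_covariance(tree)
    rng = np.random.default_rng(params.seed)
    cols = [f"trait{i}" for i in range(params.n_traits)]
    if params.sigma2 == 0:
        return pd.DataFrame(0.0, index=tips, columns=cols)
    # tiny jitter keeps Cholesky stable when delta-transforms collapse depths
    L = np.linalg.cholesky(params.sigma2 * c + 1e-12 * np.eye(len(tips)))
    z = rng.standard_normal((len(tips), params.n_traits))
    return pd.DataFrame(L @ z, index=tips, columns=cols)


def blomberg_k(tree: TreeNode, traits: pd.DataFrame) -> SignalEstimate:
    """Blomberg's K for each trait column, on the given tree.

    K = [MSE0/MSE]_obs / [MSE0/MSE]_exp with the GLS root estimate
    a = (1'C^-1 x)/(1'C^-1 1), MSE0 = sum (x-a)^2 / (n-1),
    MSE = (x-a)' C^-1 (x-a) / (n-1), and
    [MSE0/MSE]_exp = (tr C - n / (1'C^-1 1)) / (n-1).
    """
    tips, c = bm_covariance(tree)
    if len(tips) < 4:
        raise ValueError("Blomberg K requires at least 4 tips")
    x = traits.loc[tips].to_numpy(dtype=float)
    if np.any(np.ptp(x, axis=0) == 0):
        raise ValueError("Blomberg K is undefined for a constant trait")
    n = len(tips)
    cinv = np.linalg.inv(c)
    ones = np.ones(n)
    denom_root = ones @ cinv @ ones
    expected = (np.trace(c) - n / denom_root) / (n - 1)
    ks = []
    for j in range(x.shape[1]):
        xj = x[:, j]
        a = (ones @ cinv @ xj) / denom_root
        r = xj - a
        mse0 = (r @ r) / (n - 1)
        mse = (r @ cinv @ r) / (n - 1)
        ks.append((mse0 / mse) / expected)
    return SignalEstimate(blomberg_k=np.asarray(ks))


def simulate_host_trait(
    tree: TreeNode, params: TraitEvolParams
) -> tuple[pd.DataFrame, SignalEstimate]:
    """Delta-transform the tree, run BM on it, and measure realized signal.

    K is computed on the ORIGINAL (untransformed) tree — the tree all
    downstream phylogenetic distances use — so it describes the signal the
    detection tests can exploit.
    """
    transformed = delta_transform(tree, params.delta)
    traits = simulate_bm(transformed, params)
    signal = blomberg_k(tree, traits)
    return traits, signal


def rescale_microbe_traits(
    microbe_traits: pd.DataFrame, host_traits: pd.DataFrame
) -> pd.DataFrame:
    """Affine min-max map of microbial preferences onto the host-trait range.

    Applied per trait dimension; preserves order.  Keeps host traits and
    microbial preferences on a common scale so the Gaussian niche kernel is
    meaningful.
    """
    if microbe_traits.empty or host_traits.empty:
        raise ValueError("trait tables must be non-empty")
    out = {}
    for col_m, col_h in zip(microbe_traits.columns, host_traits.columns):
        m = microbe_traits[col_m].to_numpy(dtype=float)
        h = host_traits[col_h].to_numpy(dtype=float)
        h_lo, h_hi = h.min(), h.max()
        m_lo, m_hi = m.min(), m.max()
        if h_hi == h_lo:
            raise ValueError(f"host trait {col_h!r} has zero range")
        if m_hi == m_lo:
            raise ValueError(f"microbe trait {col_m!r} has zero range")
        out[col_m] = h_lo + (m - m_lo) * (h_hi - h_lo) / (m_hi - m_lo)
    return pd.DataFrame(out, index=microbe_traits.index)


# -- plain-text IO ----------------------------------------------------------


def read_tree(path) -> TreeNode:
    return TreeNode.read(str(path), format="newick")


def write_tree(tree: TreeNode, path) -> None:
    tree.write(str(path), format="newick")


def read_traits(path) -> pd.DataFrame:
    """Tab-separated trait table: first column tip label, one column per trait."""
    return pd.read_csv(path, sep="\t", index_col=0)


def write_traits(traits: pd.DataFrame, path) -> None:
    traits.to_csv(path, sep="\t")
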