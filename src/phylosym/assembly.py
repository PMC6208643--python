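"""Individual-based assembly of one microbial community per host.

Each host draws its community from an infinite, unbiased source pool of
microbe species.  At every time step the whole community of K individuals is
redrawn multinomially with recruitment probabilities that mix three
normalized components — environmental filtering (Gaussian match between host
trait and microbial preference), abundance-based reproduction, and
competition (niche overlap with residents) — weighted by beta.env, beta.abun
and beta.comp.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "AssemblyParams",
    "environmental_fitness",
    "competition_penalty",
    "recruitment_probabilities",
    "assemble_community",
    "assemble_system",
    "read_communities",
    "write_communities",
]


@dataclass(frozen=True)
class AssemblyParams:
    """Knobs of the assembly model.

    niche_breadth : SD (trait units) of the Gaussian niche kernels.
    beta_env / beta_abun / beta_comp : nonnegative weights of the
        environmental, reproduction and competition filters.
    years : number of time steps (whole-community redraws).
    capacity : carrying capacity K — individuals per host community.
    """

    niche_breadth: float = 0.5
    beta_env: float = 1.0
    beta_abun: float = 0.0
    beta_comp: float = 0.0
    years: int = 20
    capacity: int = 150
    seed: int = 0

    def __post_init__(self) -> None:
        if self.niche_breadth <= 0:
            raise ValueError("niche_breadth must be positive")
        for name in ("beta_env", "beta_abun", "beta_comp"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        if self.years < 1 or self.capacity < 1:
            raise ValueError("years and capacity must be positive integers")


def _gaussian_kernel(delta2: np.ndarray, sigma: float) -> np.ndarray:
    return np.exp(-delta2 / (2.0 * sigma * sigma))


def environmental_fitness(
    host_trait: np.ndarray, microbe_prefs: pd.DataFrame, niche_breadth: float
) -> np.ndarray:
    """Gaussian niche match between one host and every microbe, in [0, 1].

    Multi-trait fitness is the product of per-trait kernels (a diagonal
    multivariate Gaussian niche); equals 1 iff preferences match the host
    trait exactly on every dimension.
    """
    if niche_breadth <= 0:
        raise ValueError("niche_breadth must be positive")
    h = np.atleast_1d(np.asarray(host_trait, dtype=float))
    m = microbe_prefs.to_numpy(dtype=float)
    if m.shape[1] != h.shape[0]:
        raise ValueError(
            f"host has {h.shape[0]} trait(s) but microbes have {m.shape[1]}"
        )
    per_trait = _gaussian_kernel((m - h) ** 2, niche_breadth)
    return per_trait.prod(axis=1)


def niche_overlap_matrix(
    microbe_prefs: pd.DataFrame, niche_breadth: float
) -> np.ndarray:
    """Pairwise Gaussian niche overlap among microbes (1 on the diagonal)."""
    m = microbe_prefs.to_numpy(dtype=float)
    d2 = ((m[:, None, :] - m[None, :, :]) ** 2).sum(axis=2)
    return _gaussian_kernel(d2, niche_breadth)


def competition_penalty(
    abundances: np.ndarray,
    microbe_prefs: pd.DataFrame,
    niche_breadth: float,
    overlap: np.ndarray | None = None,
) -> np.ndarray:
    """1 minus abundance-weighted niche overlap with the resident community.

    An empty community exerts no competition (all ones); a community of K
    copies of microbe i fully suppresses i (penalty 0).
    """
    a = np.asarray(abundances, dtype=float)
    if overlap is None:
        overlap = niche_overlap_matrix(microbe_prefs, niche_breadth)
    total = a.sum()
    if total == 0:
        return np.ones(len(a))
    return 1.0 - (overlap @ a) / total


def _normalize_or_zero(v: np.ndarray) -> np.ndarray:
    s = v.sum()
    return v / s if s > 0 else np.zeros_like(v)


def recruitment_probabilities(
    env_fit: np.ndarray,
    abundances: np.ndarray,
    comp_pen: np.ndarray,
    params: AssemblyParams,
) -> np.ndarray:
    """Convex additive mixture of the normalized filter components.

    p ∝ beta_env*Ê + beta_abun*Â + beta_comp*Ĉ, each component normalized to
    sum 1 (a component with zero total mass contributes nothing).  Falls back
    to the uniform distribution when all mass vanishes or all betas are 0.
    """
    env_fit = np.asarray(env_fit, dtype=float)
    abundances = np.asarray(abundances, dtype=float)
    comp_pen = np.asarray(comp_pen, dtype=float)
    if min(env_fit.min(), abundances.min(), comp_pen.min()) < 0:
        raise ValueError("component vectors must be nonnegative")
    p = (
        params.beta_env * _normalize_or_zero(env_fit)
        + params.beta_abun * _normalize_or_zero(abundances)
        + params.beta_comp * _normalize_or_zero(comp_pen)
    )
    s = p.sum()
    if s == 0:
        return np.full(len(env_fit), 1.0 / len(env_fit))
    return p / s


def assemble_community(
    host_trait: np.ndarray,
    microbe_prefs: pd.DataFrame,
    params: AssemblyParams,
    seed: int | np.random.Generator | None = None,
    _env_fit: np.ndarray | None = None,
    _overlap: np.ndarray | None = None,
) -> np.ndarray:
    """Assemble one host's community of ``params.capacity`` individuals.

    Starts empty (first-step recruitment is environmental and/or uniform) and
    redraws the full community multinomially for ``params.years`` steps.
    With beta_abun = beta_comp = 0 the dynamics collapse to a single
    multinomial draw with p = Ê, whatever the number of steps.
    """
    rng = np.random.default_rng(params.seed if seed is None else seed)
    if _env_fit is None:
        _env_fit = environmental_fitness(host_trait, microbe_prefs, params.niche_breadth)
    m = len(_env_fit)
    need_comp = params.beta_comp > 0
    if need_comp and _overlap is None:
        _overlap = niche_overlap_matrix(microbe_prefs, params.niche_breadth)
    abundances = np.zeros(m)
    for _ in range(params.years):
        if need_comp:
            comp = competition_penalty(
                abundances, microbe_prefs, params.niche_breadth, overlap=_overlap
            )
            comp = np.clip(comp, 0.0, 1.0)
        else:
            comp = np.ones(m)
        p = recruitment_probabilities(_env_fit, abundances, comp, params)
        abundances = rng.multinomial(params.capacity, p).astype(float)
    return abundances.astype(int)


def assemble_system(
    host_traits: pd.DataFrame,
    microbe_prefs: pd.DataFrame,
    params: AssemblyParams,
) -> pd.DataFrame:
    """Assemble every host's community independently.

    Per-host RNG streams are spawned from ``params.seed`` so the result is a
    pure function of (traits, params) and adding hosts never perturbs the
    communities of existing ones.  Returns a hosts x microbes integer
    DataFrame whose rows each sum to the carrying capacity.
    """
    overlap = (
        niche_overlap_matrix(microbe_prefs, params.niche_breadth)
        if params.beta_comp > 0
        else None
    )
    streams = np.random.SeedSequence(params.seed).spawn(len(host_traits))
    rows = {}
    for (host, trait), ss in zip(host_traits.iterrows(), streams):
        env = environmental_fitness(
            trait.to_numpy(dtype=float), microbe_prefs, params.niche_breadth
        )
        rows[host] = assemble_community(
            trait.to_numpy(dtype=float),
            microbe_prefs,
            params,
            seed=np.random.default_rng(ss),
            _env_fit=env,
            _overlap=overlap,
        )
    return pd.DataFrame.from_dict(
        rows, orient="index", columns=microbe_prefs.index
    ).astype(int)


def read_communities(path) -> pd.DataFrame:
    """Tab-separated community table: hosts as rows, microbes as columns."""
    return pd.read_csv(path, sep="\t", index_col=0).astype(int)


def write_communities(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t")
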