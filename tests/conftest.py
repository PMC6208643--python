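"""Shared fixtures.

The two Monte Carlo pools reproduce the package's standard study conditions
(25 hosts, 150 microbes, niche breadth 0.5, 20 steps, capacity 150, weighted
UniFrac, 999 permutations) once per session; several statistical tests
aggregate over them.
"""

import numpy as np
import pytest
from skbio import TreeNode

from phylosym import runner, treesim

NEUTRAL_SEED = 101
FILTERING_SEED = 202


@pytest.fixture(scope="session")
def neutral_pool():
    """500 neutral-control replicates (beta_env=0, beta_abun=1), both
    dendrogram nulls."""
    return runner.neutral_study(n_replicates=500, seed=NEUTRAL_SEED)


@pytest.fixture(scope="session")
def filtering_pool():
    """Filtering-preset replicates over the delta grid until the moderate
    and strong Blomberg-K bins each hold >= 200 replicates."""
    return runner.filtering_study(min_per_bin=200, seed=FILTERING_SEED)


@pytest.fixture(scope="session")
def filtering_binned(filtering_pool):
    df = filtering_pool[~filtering_pool["failed"]]
    return runner.bin_by_signal(df)


@pytest.fixture
def tree25():
    """A fixed 25-tip unit-height Yule tree."""
    return treesim.simulate_yule_tree(25, seed=42)


@pytest.fixture
def balanced4() -> TreeNode:
    """Balanced 4-tip ultrametric tree, both splits at depth 0.5."""
    return TreeNode.read(["((a:0.5,b:0.5):0.5,(c:0.5,d:0.5):0.5);"])


def random_traits(tree, seed):
    rng = np.random.default_rng(seed)
    tips = [t.name for t in tree.tips()]
    import pandas as pd

    return pd.DataFrame({"trait0": rng.standard_normal(len(tips))}, index=tips)
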