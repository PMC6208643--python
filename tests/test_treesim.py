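"""Tree simulation, delta transform, Brownian traits and Blomberg K."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from skbio import TreeNode

from phylosym import treesim
from phylosym.treesim import (
    TraitEvolParams,
    blomberg_k,
    bm_covariance,
    delta_transform,
    rescale_microbe_traits,
    simulate_bm,
    simulate_host_trait,
    simulate_yule_tree,
)


def tip_depths(tree):
    return {t.name: tree.distance(t) for t in tree.tips()}


class TestYule:
    @pytest.mark.parametrize("n_tips", [2, 5, 25, 150])
    def test_ultrametric_unit_height_binary(self, n_tips):
        tree = simulate_yule_tree(n_tips, seed=3)
        depths = np.array(list(tip_depths(tree).values()))
        assert np.allclose(depths, 1.0, rtol=1e-9)
        assert tree.count(tips=True) == n_tips
        internal = sum(1 for _ in tree.non_tips(include_self=True))
        assert internal == n_tips - 1  # rooted binary
        for node in tree.non_tips(include_self=True):
            assert len(node.children) == 2

    def test_two_tips_is_a_cherry(self):
        tree = simulate_yule_tree(2, seed=0)
        assert sorted(t.name for t in tree.tips()) == ["t1", "t2"]
        assert all(d == pytest.approx(1.0) for d in tip_depths(tree).values())

    def test_degenerate_input(self):
        with pytest.raises(ValueError):
            simulate_yule_tree(1, seed=0)

    def test_deterministic_under_seed(self):
        a = simulate_yule_tree(10, seed=5)
        b = simulate_yule_tree(10, seed=5)
        assert str(a) == str(b)
        c = simulate_yule_tree(10, seed=6)
        assert str(a) != str(c)


class TestDeltaTransform:
    def test_identity_at_delta_one(self):
        tree = simulate_yule_tree(12, seed=1)
        out = delta_transform(tree, 1.0)
        for n1, n2 in zip(tree.postorder(), out.postorder()):
            if n1.length is not None:
                assert n2.length == pytest.approx(n1.length, abs=1e-12)

    def test_closed_form_on_three_tips(self):
        tree = TreeNode.read(["((a:0.5,b:0.5):0.5,c:1.0);"])
        out = delta_transform(tree, 2.0)
        internal = out.find("a").parent
        depth = out.distance(internal)
        assert depth == pytest.approx(0.25)  # 0.5 ** 2
        assert out.find("a").length == pytest.approx(0.75)

    def test_large_delta_collapses_to_near_star(self):
        tree = simulate_yule_tree(10, seed=2)
        out = delta_transform(tree, 1000.0)
        for node in out.non_tips(include_self=False):
            assert out.distance(node) < 1e-3
        depths = np.array(list(tip_depths(out).values()))
        assert np.allclose(depths, 1.0, rtol=1e-9)

    def test_invalid_arguments(self):
        tree = simulate_yule_tree(5, seed=0)
        with pytest.raises(ValueError):
            delta_transform(tree, 0.0)
        unscaled = TreeNode.read(["((a:1,b:1):1,c:2);"])
        with pytest.raises(ValueError):
            delta_transform(unscaled, 0.5)


class TestBrownianMotion:
    def test_zero_rate_gives_constant_zero(self):
        tree = simulate_yule_tree(6, seed=0)
        traits = simulate_bm(tree, TraitEvolParams(sigma2=0.0, seed=1))
        assert (traits.to_numpy() == 0).all()

    def test_cherry_covariance_matches_shared_depth(self):
        # a and b split at depth 0.5 -> cov(a, b) = 0.5, var = height = 1
        tree = TreeNode.read(["((a:0.5,b:0.5):0.5,c:1.0);"])
        vals = np.array(
            [
                simulate_bm(tree, TraitEvolParams(seed=s))
                .loc[["a", "b"], "trait0"]
                .to_numpy()
                for s in range(10_000)
            ]
        )
        cov = np.cov(vals.T)
        assert cov[0, 1] == pytest.approx(0.5, abs=0.05)
        assert cov[0, 0] == pytest.approx(1.0, abs=0.05)
        assert cov[1, 1] == pytest.approx(1.0, abs=0.05)

    def test_deterministic_under_seed(self):
        tree = simulate_yule_tree(8, seed=3)
        p = TraitEvolParams(n_traits=2, seed=9)
        pd.testing.assert_frame_equal(simulate_bm(tree, p), simulate_bm(tree, p))

    def test_covariance_matrix_is_mrca_depth(self):
        tree = TreeNode.read(["((a:0.5,b:0.5):0.5,c:1.0);"])
        tips, c = bm_covariance(tree)
        df = pd.DataFrame(c, index=tips, columns=tips)
        assert df.loc["a", "b"] == pytest.approx(0.5)
        assert df.loc["a", "c"] == pytest.approx(0.0)
        assert df.loc["a", "a"] == pytest.approx(1.0)


def dense_gls_k(tree, x):
    """Independent Blomberg-K oracle: explicit dense inverses, no shortcuts."""
    tips, c = bm_covariance(tree)
    x = np.asarray([x[t] for t in tips], dtype=float)
    n = len(tips)
    cinv = np.linalg.inv(c)
    ones = np.ones(n)
    a = (ones @ cinv @ x) / (ones @ cinv @ ones)
    mse0 = float((x - a) @ (x - a)) / (n - 1)
    mse = float((x - a) @ cinv @ (x - a)) / (n - 1)
    expected = (np.trace(c) - n / (ones @ cinv @ ones)) / (n - 1)
    return (mse0 / mse) / expected


class TestBlombergK:
    def test_balanced_four_tip_matches_gls_oracle(self, balanced4):
        traits = pd.DataFrame(
            {"trait0": [1.0, 1.0, -1.0, -1.0]}, index=["a", "b", "c", "d"]
        )
        k = blomberg_k(balanced4, traits).blomberg_k[0]
        oracle = dense_gls_k(balanced4, traits["trait0"].to_dict())
        assert k == pytest.approx(oracle, rel=1e-12)

    @pytest.mark.parametrize("n_tips", [4, 5, 6])
    def test_agrees_with_oracle_on_random_trees(self, n_tips):
        for seed in range(10):
            tree = simulate_yule_tree(n_tips, seed=seed)
            rng = np.random.default_rng(seed + 100)
            traits = pd.DataFrame(
                {"trait0": rng.standard_normal(n_tips)},
                index=[t.name for t in tree.tips()],
            )
            k = blomberg_k(tree, traits).blomberg_k[0]
            oracle = dense_gls_k(tree, traits["trait0"].to_dict())
            assert k == pytest.approx(oracle, rel=1e-8)

    def test_constant_trait_is_degenerate(self, balanced4):
        traits = pd.DataFrame({"trait0": [2.0] * 4}, index=["a", "b", "c", "d"])
        with pytest.raises(ValueError):
            blomberg_k(balanced4, traits)

    def test_permuting_tips_destroys_signal(self, tree25):
        rng = np.random.default_rng(0)
        tips = [t.name for t in tree25.tips()]
        k_bm, k_perm = [], []
        for s in range(500):
            traits = simulate_bm(tree25, TraitEvolParams(seed=s))
            k_bm.append(blomberg_k(tree25, traits).blomberg_k[0])
            shuffled = traits.copy()
            shuffled.index = rng.permutation(tips)
            k_perm.append(blomberg_k(tree25, shuffled).blomberg_k[0])
        assert np.mean(k_perm) < np.mean(k_bm)

    def test_matches_r_picante(self, tree25, tmp_path):
        """Cross-check against the reference R implementation (picante)."""
        import shutil
        import subprocess

        if shutil.which("Rscript") is None:
            pytest.skip("Rscript not available")
        traits = simulate_bm(tree25, TraitEvolParams(seed=7))
        k = blomberg_k(tree25, traits).blomberg_k[0]
        tree25.write(str(tmp_path / "tree.nwk"))
        traits.to_csv(tmp_path / "traits.tsv", sep="\t")
        script = (
            'suppressMessages(library(picante)); '
            f'tr <- read.tree("{tmp_path}/tree.nwk"); '
            f'x <- read.table("{tmp_path}/traits.tsv", header=TRUE, row.names=1); '
            "v <- setNames(x$trait0, rownames(x)); "
            "cat(Kcalc(v[tr$tip.label], tr))"
        )
        out = subprocess.run(
            ["Rscript", "-e", script], capture_output=True, text=True, check=True
        )
        assert k == pytest.approx(float(out.stdout.strip()), rel=1e-6)


class TestHostTraitSignal:
    def test_mean_k_near_one_under_plain_bm(self, tree25):
        ks = [
            simulate_host_trait(tree25, TraitEvolParams(delta=1.0, seed=s))[1].mean_k
            for s in range(1000)
        ]
        assert np.mean(ks) == pytest.approx(1.0, abs=0.1)

    def test_median_k_decreases_with_delta(self, tree25):
        medians = []
        for delta in (0.01, 1.0, 1000.0):
            ks = [
                simulate_host_trait(
                    tree25, TraitEvolParams(delta=delta, seed=s)
                )[1].mean_k
                for s in range(500)
            ]
            medians.append(np.median(ks))
        assert medians[0] > medians[1] > medians[2]

    def test_deterministic(self, tree25):
        p = TraitEvolParams(delta=0.1, seed=13)
        t1, s1 = simulate_host_trait(tree25, p)
        t2, s2 = simulate_host_trait(tree25, p)
        pd.testing.assert_frame_equal(t1, t2)
        assert s1.blomberg_k == pytest.approx(s2.blomberg_k)


class TestRescaleMicrobeTraits:
    def test_identity_when_ranges_match(self):
        host = pd.DataFrame({"trait0": [-1.0, 0.3, 1.0]}, index=list("abc"))
        microbe = pd.DataFrame({"trait0": [-1.0, 0.0, 1.0]}, index=list("xyz"))
        out = rescale_microbe_traits(microbe, host)
        pd.testing.assert_frame_equal(out, microbe)

    def test_closed_form_affine_map(self):
        host = pd.DataFrame({"trait0": [-1.0, 1.0]}, index=list("ab"))
        microbe = pd.DataFrame({"trait0": [0.0, 5.0, 10.0]}, index=list("xyz"))
        out = rescale_microbe_traits(microbe, host)
        assert out["trait0"].tolist() == pytest.approx([-1.0, 0.0, 1.0])

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_output_spans_host_range(self, seed):
        rng = np.random.default_rng(seed)
        host = pd.DataFrame(
            {"trait0": rng.normal(size=6)}, index=[f"h{i}" for i in range(6)]
        )
        microbe = pd.DataFrame(
            {"trait0": rng.normal(2, 5, size=9)}, index=[f"m{i}" for i in range(9)]
        )
        out = rescale_microbe_traits(microbe, host)
        assert out["trait0"].min() == pytest.approx(host["trait0"].min())
        assert out["trait0"].max() == pytest.approx(host["trait0"].max())
        # order preserved
        assert (
            out["trait0"].rank().tolist() == microbe["trait0"].rank().tolist()
        )

    def test_zero_host_range_is_degenerate(self):
        host = pd.DataFrame({"trait0": [1.0, 1.0]}, index=list("ab"))
        microbe = pd.DataFrame({"trait0": [0.0, 5.0]}, index=list("xy"))
        with pytest.raises(ValueError):
            rescale_microbe_traits(microbe, host)


class TestNewickRoundTrip:
    def test_tree_round_trip(self, tmp_path, tree25):
        path = tmp_path / "t.nwk"
        treesim.write_tree(tree25, path)
        back = treesim.read_tree(path)
        assert sorted(t.name for t in back.tips()) == sorted(
            t.name for t in tree25.tips()
        )
        for t in back.tips():
            assert back.distance(t) == pytest.approx(1.0, rel=1e-6)

    def test_trait_table_round_trip(self, tmp_path):
        traits = pd.DataFrame(
            {"trait0": [0.1, -2.3], "trait1": [4.5, 0.0]}, index=["t1", "t2"]
        )
        path = tmp_path / "traits.tsv"
        treesim.write_traits(traits, path)
        pd.testing.assert_frame_equal(treesim.read_traits(path), traits)
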