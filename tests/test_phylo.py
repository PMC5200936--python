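"""Tree I/O, midpoint rooting, pruning, contrasts, BM simulation."""

import math

import dendropy
import numpy as np
import pytest

import digiprot as dp
from digiprot import phylo as ph

from conftest import random_bifurcating_tree


def gls_slope(tree: ph.PhyloTree, x: dict, y: dict) -> float:
    """Independent oracle: GLS slope under the full BM covariance matrix."""
    leaves = tree.leaves()
    names = [l.name for l in leaves]

    def root_path(leaf):
        path = []
        cur = leaf
        while cur is not None:
            path.append(cur)
            cur = cur.parent
        return path[::-1]

    paths = {l.name: root_path(l) for l in leaves}
    n = len(names)
    C = np.zeros((n, n))
    for i, a in enumerate(names):
        for j, b in enumerate(names):
            if i == j:
                C[i, j] = sum(nd.length for nd in paths[a] if nd.parent is not None)
                continue
            shared = 0.0
            for u, v in zip(paths[a], paths[b]):
                if u is v:
                    if u.parent is not None:
                        shared += u.length
                else:
                    break
            C[i, j] = shared
    X = np.column_stack([np.ones(n), [x[nm] for nm in names]])
    yv = np.array([y[nm] for nm in names])
    Ci = np.linalg.inv(C)
    beta = np.linalg.solve(X.T @ Ci @ X, X.T @ Ci @ yv)
    return float(beta[1])


class TestNewickIO:
    def test_basic_parse(self):
        t = dp.read_newick("((A:1,B:1):1,C:2);")
        assert sorted(t.leaf_names()) == ["A", "B", "C"]
        assert t.n_leaves == 3
        assert t.is_bifurcating

    def test_roundtrip_random_trees(self):
        rng = np.random.default_rng(5)
        for _ in range(100):
            t = random_bifurcating_tree(int(rng.integers(2, 12)), rng)
            text = dp.write_newick(t)
            back = dp.read_newick(text)
            assert sorted(back.leaf_names()) == sorted(t.leaf_names())
            assert back.total_length() == pytest.approx(t.total_length(), abs=1e-10)
            assert dp.write_newick(back) == text

    def test_single_leaf_flagged_unusable(self):
        t = dp.read_newick("(A:1);")
        assert t.n_leaves == 1
        assert not t.usable_for_contrasts

    def test_malformed_raises(self):
        with pytest.raises(dp.NewickParseError):
            dp.read_newick("((A:1,B:1;")

    def test_duplicate_leaves_rejected(self):
        with pytest.raises(dp.NewickParseError, match="duplicate"):
            dp.read_newick("(A:1,A:2);")


class TestMidpointRoot:
    def test_symmetric_two_leaves(self):
        r = dp.midpoint_root(dp.read_newick("(A:2,B:2);"))
        depths = {l.name: l.length for l in r.leaves()}
        assert depths == {"A": 2.0, "B": 2.0}

    def test_asymmetric_two_leaves(self):
        r = dp.midpoint_root(dp.read_newick("(A:1,B:3);"))
        depths = {l.name: l.length for l in r.leaves()}
        assert depths["A"] == pytest.approx(2.0)
        assert depths["B"] == pytest.approx(2.0)

    def test_idempotent(self):
        t = dp.read_newick("((A:1,B:1):1,C:2);")
        once = dp.midpoint_root(t)
        twice = dp.midpoint_root(once)
        assert dp.write_newick(once) == dp.write_newick(twice)

    def test_total_length_conserved(self):
        rng = np.random.default_rng(17)
        for _ in range(20):
            t = random_bifurcating_tree(int(rng.integers(3, 15)), rng)
            r = dp.midpoint_root(t)
            assert r.total_length() == pytest.approx(t.total_length(), abs=1e-9)

    def test_matches_dendropy(self):
        """Leaf depths after rooting agree with dendropy's midpoint rooter."""
        rng = np.random.default_rng(23)
        for _ in range(10):
            t = random_bifurcating_tree(int(rng.integers(4, 12)), rng)
            mine = dp.midpoint_root(t)

            def depths(tree):
                out = {}

                def walk(n, acc):
                    for c in n.children:
                        walk(c, acc + c.length)
                    if n.is_leaf:
                        out[n.name] = acc

                walk(tree.root, 0.0)
                return out

            dt = dendropy.Tree.get(data=dp.write_newick(t), schema="newick")
            dt.reroot_at_midpoint(update_bipartitions=False)
            dd = {
                l.taxon.label: l.distance_from_root() for l in dt.leaf_node_iter()
            }
            mm = depths(mine)
            for name in mm:
                assert mm[name] == pytest.approx(dd[name], abs=1e-8)

    def test_all_zero_lengths_error(self):
        with pytest.raises(dp.TreeStructureError):
            dp.midpoint_root(dp.read_newick("(A:0,B:0);"))


class TestPruneZeroBranches:
    def test_suppression_arithmetic(self):
        t = dp.read_newick("((A:0,B:1):1,C:2);")
        pruned, removed = dp.prune_zero_branches(t)
        assert removed == ["A"]
        depths = {l.name: l.length for l in pruned.leaves()}
        assert depths == {"B": 2.0, "C": 2.0}

    def test_identity_without_zero_branches(self):
        t = dp.read_newick("((A:1,B:1):1,C:2);")
        pruned, removed = dp.prune_zero_branches(t)
        assert removed == []
        assert dp.write_newick(pruned) == dp.write_newick(t)

    def test_idempotent(self):
        t = dp.read_newick("((A:0,B:1):1,(C:2,D:0.5):1);")
        once, removed = dp.prune_zero_branches(t)
        twice, removed2 = dp.prune_zero_branches(once)
        assert removed == ["A"] and removed2 == []
        assert dp.write_newick(once) == dp.write_newick(twice)

    def test_too_few_leaves_error(self):
        with pytest.raises(dp.TreeStructureError):
            dp.prune_zero_branches(dp.read_newick("(A:0,B:1);"))


class TestPicContrasts:
    def test_hand_worked_three_leaves(self):
        t = dp.read_newick("((A:1,B:1):1,C:2);")
        cs = dp.pic_contrasts(t, {"A": 1.0, "B": 3.0, "C": 2.0})
        vals = sorted(v for _, v in cs.contrasts)
        assert vals[0] == pytest.approx(-math.sqrt(2))
        assert vals[1] == pytest.approx(0.0)
        assert cs.n_leaves == 3

    def test_identical_traits_zero_contrasts(self):
        rng = np.random.default_rng(2)
        t = random_bifurcating_tree(10, rng)
        cs = dp.pic_contrasts(t, {n: 5.0 for n in t.leaf_names()})
        assert np.allclose(cs.values(), 0.0)

    def test_contrast_count(self):
        rng = np.random.default_rng(4)
        for n in (2, 5, 9, 16):
            t = random_bifurcating_tree(n, rng)
            traits = {nm: float(i) for i, nm in enumerate(t.leaf_names())}
            assert len(dp.pic_contrasts(t, traits).contrasts) == n - 1

    def test_polytomy_rejected(self):
        t = dp.read_newick("(A:1,B:1,C:1);")
        with pytest.raises(dp.TreeStructureError, match="polytomy"):
            dp.pic_contrasts(t, {"A": 1.0, "B": 2.0, "C": 3.0})

    def test_missing_trait_rejected(self):
        t = dp.read_newick("(A:1,B:1);")
        with pytest.raises(ValueError, match="missing"):
            dp.pic_contrasts(t, {"A": 1.0})

    def test_gls_oracle_agreement(self):
        """PIC through-origin slope equals the GLS slope with full BM
        covariance, for trees up to 8 leaves."""
        rng = np.random.default_rng(31)
        for _ in range(10):
            t = random_bifurcating_tree(int(rng.integers(3, 9)), rng)
            x, y = dp.simulate_bm(
                t, 1.0, seed=int(rng.integers(2**31)),
                coupled_slope=0.6, coupled_resid_rate=0.4,
            )
            res = dp.origin_regression(
                dp.pic_contrasts(t, y), dp.pic_contrasts(t, x)
            )
            assert res.slopes["x"] == pytest.approx(gls_slope(t, x, y), abs=1e-8)

    def test_standardization(self):
        """Contrast variance approximates the BM rate, independent of tree."""
        rng = np.random.default_rng(77)
        t = random_bifurcating_tree(40, rng)
        all_contrasts = []
        for rep in range(200):
            traits = dp.simulate_bm(t, 2.5, seed=1000 + rep)
            all_contrasts.extend(dp.pic_contrasts(t, traits).values())
        assert np.var(all_contrasts) == pytest.approx(2.5, rel=0.05)


class TestOriginRegression:
    def test_exact_proportionality(self):
        x = np.array([1.0, -2.0, 3.0, 0.5])
        res = dp.origin_regression(2 * x, x)
        assert res.slopes["x"] == pytest.approx(2.0)
        assert res.r_squared == pytest.approx(1.0)

    def test_sign_flip_invariance(self):
        rng = np.random.default_rng(6)
        x = rng.normal(0, 1, 20)
        y = 0.7 * x + rng.normal(0, 0.2, 20)
        base = dp.origin_regression(y, x)
        flipped_x, flipped_y = x.copy(), y.copy()
        flipped_x[3] *= -1
        flipped_y[3] *= -1
        flipped = dp.origin_regression(flipped_y, flipped_x)
        assert flipped.slopes["x"] == pytest.approx(base.slopes["x"])

    def test_slope_recovery_on_bm(self):
        """200 BM replicates on 100-leaf trees recover the true slope 0.5."""
        rng = np.random.default_rng(123)
        t = random_bifurcating_tree(100, rng)
        slopes = []
        for rep in range(200):
            x, y = dp.simulate_bm(
                t, 1.0, seed=rep, coupled_slope=0.5, coupled_resid_rate=0.25
            )
            res = dp.origin_regression(dp.pic_contrasts(t, y), dp.pic_contrasts(t, x))
            slopes.append(res.slopes["x"])
        assert np.mean(slopes) == pytest.approx(0.5, abs=0.05)


class TestSimulateBM:
    def test_zero_rate_constant(self):
        rng = np.random.default_rng(9)
        t = random_bifurcating_tree(8, rng)
        traits = dp.simulate_bm(t, 0.0, seed=1, root_value=3.5)
        assert all(v == 3.5 for v in traits.values())

    def test_seed_reproducibility(self):
        rng = np.random.default_rng(10)
        t = random_bifurcating_tree(12, rng)
        assert dp.simulate_bm(t, 1.3, seed=42) == dp.simulate_bm(t, 1.3, seed=42)

    def test_variance_grows_with_depth(self):
        """Empirical leaf variance matches rate x root-to-leaf depth."""
        t = dp.read_newick("(A:0.5,(B:1.5,C:1.5):2.5);")
        samples = {n: [] for n in "ABC"}
        for rep in range(3000):
            traits = dp.simulate_bm(t, 1.0, seed=rep)
            for n in samples:
                samples[n].append(traits[n])
        assert np.var(samples["A"]) == pytest.approx(0.5, rel=0.15)
        assert np.var(samples["B"]) == pytest.approx(4.0, rel=0.15)
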