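import numpy as np
import pytest
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from geneage import complete_linkage, cut_tree, to_newick
from geneage.clustering import (
    bootstrap_curve_stats,
    bootstrap_order_rates,
    bootstrap_trees,
)
from geneage.compare import DistanceMatrix
from geneage.errors import ValidationError
from geneage.synthetic import planted_groups_spec, simulate_class


def dmatrix(labels, dense):
    return DistanceMatrix(labels=tuple(labels), d=np.asarray(dense, dtype=float))


def random_dmatrix(rng, m):
    """Random distances without exact ties (generic position)."""
    cond = rng.uniform(0.05, 0.95, size=m * (m - 1) // 2)
    return dmatrix([f"c{i}" for i in range(m)], squareform(cond)), cond


class TestCompleteLinkage:
    def test_hand_agglomeration(self):
        dm = dmatrix("ABC", [[0, 0.1, 0.9], [0.1, 0, 0.8], [0.9, 0.8, 0]])
        tree = complete_linkage(dm)
        assert tree.height == pytest.approx(0.9)  # complete linkage takes max(0.9, 0.8)
        inner = next(c for c in tree.children if not c.is_leaf)
        assert inner.leaves == frozenset("AB") and inner.height == pytest.approx(0.1)

    def test_two_labels_single_merge(self):
        tree = complete_linkage(dmatrix("AB", [[0, 0.3], [0.3, 0]]))
        assert tree.height == pytest.approx(0.3)
        assert tree.leaves == frozenset("AB")

    def test_heights_nondecreasing_to_root(self, rng):
        for _ in range(20):
            dm, _ = random_dmatrix(rng, 8)
            tree = complete_linkage(dm)
            for node in tree.internal_nodes():
                for child in node.children:
                    assert child.height <= node.height + 1e-12

    def test_matches_scipy_merge_heights_and_clades(self, rng):
        for _ in range(20):
            dm, cond = random_dmatrix(rng, 7)
            tree = complete_linkage(dm)
            Z = hierarchy.linkage(cond, method="complete")
            ours = sorted(n.height for n in tree.internal_nodes())
            scipys = sorted(Z[:, 2])
            assert np.allclose(ours, scipys)
            # same clades
            scipy_tree = hierarchy.to_tree(Z)
            def clades(node, acc):
                if node.is_leaf():
                    return {node.id}
                left = clades(node.get_left(), acc)
                right = clades(node.get_right(), acc)
                acc.append(left | right)
                return left | right
            acc = []
            clades(scipy_tree, acc)
            scipy_clades = {frozenset(dm.labels[i] for i in s) for s in acc}
            assert tree.clades() == scipy_clades

    def test_invariant_under_label_permutation(self, rng):
        dm, _ = random_dmatrix(rng, 6)
        perm = rng.permutation(6)
        dm2 = DistanceMatrix(
            labels=tuple(dm.labels[i] for i in perm), d=dm.d[np.ix_(perm, perm)]
        )
        assert complete_linkage(dm).clades() == complete_linkage(dm2).clades()

    def test_nan_distance_rejected(self):
        with pytest.raises(ValidationError, match="NaN"):
            complete_linkage(dmatrix("AB", [[0, np.nan], [np.nan, 0]]))


class TestNewick:
    def test_three_leaf_hand_layout(self):
        dm = dmatrix("ABC", [[0, 0.1, 0.9], [0.1, 0, 0.8], [0.9, 0.8, 0]])
        assert to_newick(complete_linkage(dm)) == "((A:0.1,B:0.1):0.8,C:0.9);"

    def test_two_leaf_tree(self):
        assert to_newick(complete_linkage(dmatrix("AB", [[0, 0.5], [0.5, 0]]))) == "(A:0.5,B:0.5);"

    def test_round_trip_through_dendropy(self, rng):
        import dendropy

        dm, _ = random_dmatrix(rng, 6)
        tree = complete_linkage(dm)
        nwk = to_newick(tree)
        parsed = dendropy.Tree.get(data=nwk, schema="newick")
        assert {leaf.taxon.label for leaf in parsed.leaf_node_iter()} == set(dm.labels)
        # ultrametric: every leaf sits at the root height
        depths = [leaf.distance_from_root() for leaf in parsed.leaf_node_iter()]
        assert np.allclose(depths, tree.height, atol=1e-6)

    def test_write_parse_write_idempotent(self, rng):
        import dendropy

        dm, _ = random_dmatrix(rng, 5)
        nwk = to_newick(complete_linkage(dm))
        parsed = dendropy.Tree.get(data=nwk, schema="newick")
        again = parsed.as_string(schema="newick", suppress_rooting=True).strip()
        reparsed = dendropy.Tree.get(data=again, schema="newick")
        assert reparsed.as_string(schema="newick", suppress_rooting=True).strip() == again


class TestBootstrapTrees:
    def test_point_mass_classes_fully_supported(self, tl16):
        ages = {
            "a": np.full(30, 1), "b": np.full(30, 8), "c": np.full(30, 16),
        }
        boot = bootstrap_trees(ages, tl16, n_boot=50, seed=0)
        assert all(s == 1.0 for s in boot.node_support.values())

    def test_support_in_unit_interval_and_root_certain(self, tl16, rng):
        ages = {f"c{i}": rng.integers(1, 17, size=80) for i in range(5)}
        boot = bootstrap_trees(ages, tl16, n_boot=100, seed=1)
        assert all(0.0 <= s <= 1.0 for s in boot.node_support.values())
        assert boot.node_support[frozenset(ages)] == 1.0

    def test_planted_groups_recovered_with_high_support(self, tl16):
        rng = np.random.default_rng(12)
        specs = planted_groups_spec(n_per_class=200, classes_per_group=2)
        ages = {s.name: simulate_class(s, tl16, seed=int(rng.integers(2**31)))[1] for s in specs}
        boot = bootstrap_trees(ages, tl16, n_boot=200, seed=2)
        for family in ("old", "mid", "young"):
            clade = frozenset(n for n in ages if n.startswith(family))
            assert boot.node_support.get(clade, 0.0) >= 0.95

    def test_bit_reproducible_under_seed(self, tl16, rng):
        ages = {f"c{i}": rng.integers(1, 17, size=50) for i in range(4)}
        b1 = bootstrap_trees(ages, tl16, n_boot=80, seed=7)
        b2 = bootstrap_trees(ages, tl16, n_boot=80, seed=7)
        assert b1.node_support == b2.node_support


class TestBootstrapOrderRates:
    def test_maximal_separation_rate_one(self, tl16):
        rates = bootstrap_order_rates(np.full(60, 16), np.full(60, 1), tl16, n_boot=200, seed=0)
        assert rates["A_lower"] == 1.0

    def test_identical_point_mass_no_strict_order(self, tl16):
        a = np.full(40, 5)
        rates = bootstrap_order_rates(a, a.copy(), tl16, n_boot=100, seed=1)
        assert rates["no_strict_order"] == 1.0

    def test_rates_partition_unity(self, tl16, rng):
        a = rng.integers(1, 17, size=100)
        b = rng.integers(1, 17, size=120)
        rates = bootstrap_order_rates(a, b, tl16, n_boot=300, seed=2)
        assert sum(rates.values()) == pytest.approx(1.0)


class TestBootstrapCurveStats:
    def test_point_mass_class_zero_mse(self, tl16):
        stats_ = bootstrap_curve_stats(np.full(50, 9), tl16, n_boot=100, seed=0)
        assert (stats_["mse"] == 0.0).all()

    def test_bootstrap_mean_tracks_original_curve(self, tl16, rng):
        ages = rng.integers(1, 17, size=200)
        n_boot = 500
        stats_ = bootstrap_curve_stats(ages, tl16, n_boot=n_boot, seed=1)
        sd = np.sqrt(stats_["mse"])
        tol = 3 * sd / np.sqrt(n_boot) + 1e-12
        assert (np.abs(stats_["boot_mean"] - stats_["original"]) <= tol).all()

    def test_quartiles_ordered(self, tl16, rng):
        stats_ = bootstrap_curve_stats(rng.integers(1, 17, size=80), tl16, n_boot=200, seed=2)
        assert (stats_["q25"] <= stats_["median"]).all()
        assert (stats_["median"] <= stats_["q75"]).all()


def test_cut_tree_three_groups(tl16):
    rng = np.random.default_rng(3)
    specs = planted_groups_spec(n_per_class=200, classes_per_group=2)
    ages = {s.name: simulate_class(s, tl16, seed=int(rng.integers(2**31)))[1] for s in specs}
    from geneage.compare import distance_matrix
    from geneage.distributions import build_distribution

    dists = [build_distribution(n, v, tl16) for n, v in ages.items()]
    tree = complete_linkage(distance_matrix(dists))
    groups = cut_tree(tree, 3)
    families = {frozenset(n.split("_")[0] for n in g) for g in groups}
    assert families == {frozenset({"old"}), frozenset({"mid"}), frozenset({"young"})}
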