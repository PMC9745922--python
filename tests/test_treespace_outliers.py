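import itertools

import dendropy
import numpy as np
import pandas as pd
import pytest

from skimloci.seq_io import parse_newick
from skimloci.skim_simulator import simulate_tree
from skimloci.treespace_outliers import (
    analyze_treespace,
    build_distance_matrix,
    compare_groups,
    holm_adjust,
    mahalanobis_outliers,
    mean_support,
    nj_tree,
    p_distance_matrix,
    pcoa,
    quartet_distance,
    quartet_resolution_vector,
    rf_distance,
    tip_labels,
)


# ---------------------------------------------------------------------------
# independent quartet oracle: resolution by bipartition separation, with leaf
# sets gathered by a recursive traversal unrelated to the package's
# path-distance route
def _oracle_splits(tree):
    splits = []

    def leafset(node):
        if node.is_leaf():
            return {node.taxon.label}
        acc = set()
        for ch in node.child_nodes():
            acc |= leafset(ch)
        return acc

    all_tips = leafset(tree.seed_node)
    for node in tree.preorder_node_iter():
        if node is tree.seed_node or node.is_leaf():
            continue
        side = leafset(node)
        if 2 <= len(side) <= len(all_tips) - 2:
            splits.append((side, all_tips - side))
    return splits


def _oracle_quartet_topology(splits, quartet):
    a, b, c, d = quartet
    for side, other in splits:
        for pair, rest in (((a, b), (c, d)), ((a, c), (b, d)), ((a, d), (b, c))):
            if (set(pair) <= side and set(rest) <= other) or (
                set(pair) <= other and set(rest) <= side
            ):
                return frozenset({frozenset(pair), frozenset(rest)})
    return None  # unresolved


def oracle_quartet_distance(t1, t2):
    shared = sorted(tip_labels(t1) & tip_labels(t2))
    s1, s2 = _oracle_splits(t1), _oracle_splits(t2)
    diff = 0.0
    for quartet in itertools.combinations(shared, 4):
        q1 = _oracle_quartet_topology(s1, quartet)
        q2 = _oracle_quartet_topology(s2, quartet)
        if q1 is not None and q2 is not None:
            diff += q1 != q2
        elif (q1 is None) != (q2 is None):
            diff += 0.5
    return diff


class TestRF:
    def test_identical_trees_zero(self):
        t = parse_newick("((a,b),(c,d),(e,f));")
        assert rf_distance(t, parse_newick("((a,b),(c,d),(e,f));")) == 0

    def test_four_tip_alternative_resolutions(self):
        # each tree's single internal bipartition is unshared
        t1 = parse_newick("((a,b),(c,d));")
        t2 = parse_newick("((a,c),(b,d));")
        assert rf_distance(t1, t2) == 2

    def test_five_tip_nni_neighbors(self):
        t1 = parse_newick("(((a,b),c),(d,e));")
        t2 = parse_newick("(((a,c),b),(d,e));")
        assert rf_distance(t1, t2) == 2

    def test_tip_mismatch_lists_difference(self):
        t1 = parse_newick("((a,b),(c,d));")
        t2 = parse_newick("((a,b),(c,e));")
        with pytest.raises(ValueError, match="'d'.*'e'|'e'.*'d'"):
            rf_distance(t1, t2)

    def test_agrees_with_dendropy(self):
        """Independent cross-check against dendropy's bipartition machinery."""
        for seed in range(12):
            tns = dendropy.TaxonNamespace()
            a = simulate_tree(7, seed)
            b = simulate_tree(7, seed + 100)
            da = dendropy.Tree.get(
                data=a.as_string(schema="newick"), schema="newick",
                taxon_namespace=tns)
            db = dendropy.Tree.get(
                data=b.as_string(schema="newick"), schema="newick",
                taxon_namespace=tns)
            expected = dendropy.calculate.treecompare.symmetric_difference(da, db)
            assert rf_distance(a, b) == expected


class TestQuartet:
    def test_single_quartet_conflict(self):
        t1 = parse_newick("((a,b),(c,d));")
        t2 = parse_newick("((a,c),(b,d));")
        assert quartet_distance(t1, t2) == (1.0, 1)

    def test_identical_six_tip(self):
        t = parse_newick("((a,b),((c,d),(e,f)));")
        assert quartet_distance(t, parse_newick("((a,b),((c,d),(e,f)));")) == (0.0, 15)

    def test_five_tip_nni_vs_oracle(self):
        t1 = parse_newick("(((a,b),c),(d,e));")
        t2 = parse_newick("(((a,c),b),(d,e));")
        diff, total = quartet_distance(t1, t2)
        assert total == 5
        assert diff == oracle_quartet_distance(t1, t2)

    def test_polytomy_counts_half(self):
        star = parse_newick("(a,b,c,d);")
        resolved = parse_newick("((a,b),(c,d));")
        assert quartet_distance(star, resolved) == (0.5, 1)

    def test_shared_tip_pruning(self):
        t1 = parse_newick("(((a,b),c),(d,x));")
        t2 = parse_newick("(((a,b),c),(d,y));")
        diff, total = quartet_distance(t1, t2)
        assert total == 1  # only {a,b,c,d} shared
        assert diff == 0.0

    def test_too_few_shared_tips(self):
        t1 = parse_newick("((a,b),(c,x));")
        t2 = parse_newick("((a,b),(y,z));")
        with pytest.raises(ValueError, match="shared tips"):
            quartet_distance(t1, t2)


class TestDistanceMatrix:
    def test_identical_trees_zero_matrix(self):
        t = "((a,b),((c,d),e));"
        trees = [parse_newick(t) for _ in range(3)]
        D = build_distance_matrix(trees)
        assert np.allclose(D, 0.0)

    def test_symmetric_zero_diagonal(self):
        trees = [simulate_tree(6, s) for s in range(4)]
        D = build_distance_matrix(trees)
        assert np.allclose(D, D.T) and np.allclose(np.diag(D), 0.0)

    def test_permutation_consistency(self):
        trees = [simulate_tree(6, s) for s in range(4)]
        D = build_distance_matrix(trees)
        perm = [2, 0, 3, 1]
        D2 = build_distance_matrix([trees[i] for i in perm])
        assert np.allclose(D2, D[np.ix_(perm, perm)])

    def test_rf_metric_option(self):
        trees = [simulate_tree(6, s) for s in range(3)]
        D = build_distance_matrix(trees, metric="rf")
        assert D.max() <= 1.0 and np.allclose(np.diag(D), 0.0)


class TestPcoa:
    def test_collinear_points(self):
        D = np.array([[0, 1, 2], [1, 0, 1], [2, 1, 0]], float)
        coords, eigval = pcoa(D, 3)
        assert coords.shape == (3, 1)  # one positive axis
        assert sorted(np.round(coords.ravel(), 8)) == [-1.0, 0.0, 1.0]
        assert eigval[0] == pytest.approx(2.0)

    def test_zero_matrix(self):
        coords, eigval = pcoa(np.zeros((4, 4)), 3)
        assert coords.shape[1] == 0

    def test_euclidean_distances_recovered(self):
        rng = np.random.default_rng(13)
        X = rng.normal(size=(8, 3))
        D = np.linalg.norm(X[:, None] - X[None, :], axis=2)
        coords, _ = pcoa(D, 8)
        D2 = np.linalg.norm(coords[:, None] - coords[None, :], axis=2)
        assert np.allclose(D, D2, atol=1e-8)

    def test_asymmetric_rejected(self):
        D = np.array([[0, 1], [2, 0]], float)
        with pytest.raises(ValueError, match="symmetric"):
            pcoa(D)


class TestMahalanobis:
    def test_chi_square_tail_value(self):
        # identity-covariance data: a point at squared distance 11.345 on
        # three axes has upper-tail p ~ 0.010
        rng = np.random.default_rng(14)
        X = rng.normal(size=(500, 3))
        d2, pvals, flags = mahalanobis_outliers(X, n_axes=3, alpha=0.05)
        from scipy.stats import chi2

        assert chi2.sf(11.345, 3) == pytest.approx(0.010, abs=2e-4)
        # flags correspond exactly to p < alpha
        assert np.array_equal(flags, pvals < 0.05)

    def test_single_distinct_point_flagged(self):
        X = np.vstack([np.zeros((20, 3)) + np.random.default_rng(1).normal(
            scale=0.05, size=(20, 3)), [[5, 5, 5]]])
        d2, pvals, flags = mahalanobis_outliers(X)
        assert flags[-1]

    def test_mean_point_distance_zero(self):
        rng = np.random.default_rng(15)
        X = rng.normal(size=(30, 3))
        X[0] = X[1:].mean(axis=0) * (30 / 29)  # make row 0 the column mean
        X[0] = X.mean(axis=0)
        d2, pvals, _ = mahalanobis_outliers(X)
        assert d2[0] < d2.max()

    def test_singular_covariance_raises(self):
        X = np.ones((10, 3))
        with pytest.raises(ValueError, match="fewer axes"):
            mahalanobis_outliers(X)


class TestCompareGroups:
    def test_holm_stepdown_by_hand(self):
        # sorted 0.01x3, 0.03x2, 0.04x1 with cumulative max
        assert holm_adjust([0.01, 0.04, 0.03]) == pytest.approx([0.03, 0.06, 0.06])

    def test_identical_groups_not_significant(self):
        df = pd.DataFrame({"m": np.tile([1.0, 2, 3, 4, 5], 4)})
        flags = [True] * 10 + [False] * 10
        out = compare_groups(df, flags)
        assert out.loc[0, "p_raw"] > 0.9

    def test_adjusted_at_least_raw(self):
        rng = np.random.default_rng(16)
        df = pd.DataFrame(rng.normal(size=(30, 5)), columns=list("abcde"))
        flags = [True] * 10 + [False] * 20
        out = compare_groups(df, flags)
        assert (out["p_holm"] >= out["p_raw"] - 1e-12).all()

    def test_empty_group_rejected(self):
        df = pd.DataFrame({"m": [1.0, 2.0]})
        with pytest.raises(ValueError, match="non-empty"):
            compare_groups(df, [True, True])

    def test_shifted_group_detected(self):
        rng = np.random.default_rng(17)
        df = pd.DataFrame({"m": np.concatenate(
            [rng.normal(size=30), rng.normal(loc=3, size=10)])})
        out = compare_groups(df, [False] * 30 + [True] * 10)
        assert out.loc[0, "p_holm"] < 0.01


class TestSupport:
    def test_mean_of_two(self):
        t = parse_newick("((a,b)95,(c,d)87);")
        assert mean_support(t) == pytest.approx(91.0)

    def test_single_support(self):
        t = parse_newick("((a,b)100,c,d);")
        assert mean_support(t) == 100.0

    def test_no_supports_raises(self):
        with pytest.raises(ValueError, match="support"):
            mean_support(parse_newick("((a,b),(c,d));"))


class TestNJ:
    def test_additive_four_taxon_recovery(self):
        # additive matrix satisfying the four-point condition for ab|cd
        labels = ["a", "b", "c", "d"]
        D = np.array(
            [
                [0, 2, 7, 7],
                [2, 0, 7, 7],
                [7, 7, 0, 2],
                [7, 7, 2, 0],
            ],
            float,
        )
        tree = nj_tree((labels, D))
        tips = tip_labels(tree)
        from skimloci.treespace_outliers import _nontrivial_bipartitions

        assert _nontrivial_bipartitions(tree, tips) == {
            frozenset({frozenset("ab"), frozenset("cd")})
        }

    def test_identical_sequences_star_like(self):
        rows = {f"t{i}": "ACGTACGT" for i in range(4)}
        tree = nj_tree(rows)
        assert tip_labels(tree) == set(rows)

    def test_deterministic(self):
        rng = np.random.default_rng(18)
        rows = {
            f"t{i}": "".join(rng.choice(list("ACGT"), 60)) for i in range(5)
        }
        a = nj_tree(rows).as_string(schema="newick")
        b = nj_tree(rows).as_string(schema="newick")
        assert a == b

    def test_missing_positions_ignored(self):
        rows = {"a": "ACGTNN", "b": "ACGANN", "c": "NNGTAC", "d": "NNGAAC"}
        labels, D = p_distance_matrix(rows)
        assert D[labels.index("a"), labels.index("b")] == pytest.approx(0.25)

    def test_all_missing_pair_rejected(self):
        rows = {"a": "ACNN", "b": "NNGT", "c": "ACGT", "d": "ACGT"}
        with pytest.raises(ValueError, match="comparable"):
            p_distance_matrix(rows)


class TestTreespaceEndToEnd:
    def test_planted_outliers_flagged(self):
        """Scrambled topologies sit far from a concordant gene-tree cloud."""
        base = simulate_tree(10, 40)
        concordant = []
        for i in range(25):
            t = parse_newick(base.as_string(schema="newick"))
            concordant.append(t)
        scrambled = [simulate_tree(10, 900 + i) for i in range(3)]
        # jitter the concordant cloud minimally by using NJ on noisy distances
        res = analyze_treespace(concordant + scrambled, n_axes=3, alpha=0.05)
        assert res.distances.shape == (28, 28)
        flagged = set(res.outliers())
        assert {"tree25", "tree26", "tree27"} <= flagged | set()
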