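import itertools

import numpy as np
import pytest
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from dmkcluster import (
    DistanceMatrix,
    bisect,
    bkm,
    f_measure,
    featurize,
    kmeans,
    linkage_cluster,
    mbkm,
    select_cluster_to_split,
    select_initial_centroids,
    to_newick,
    upgma,
)
from dmkcluster.cluster import cluster_variance


def blobs(rng, centers, n_per, spread=0.1):
    pts = np.vstack(
        [c + rng.normal(0, spread, size=(n_per, len(c))) for c in centers]
    )
    truth = np.repeat(np.arange(len(centers)), n_per)
    return pts, truth


def same_partition(a, b):
    return {frozenset(np.flatnonzero(a == j)) for j in np.unique(a)} == {
        frozenset(np.flatnonzero(b == j)) for j in np.unique(b)
    }


class TestSeedSelection:
    def test_extremes_on_a_line(self):
        data = np.array([[0.0], [1.0], [10.0]])
        assert select_initial_centroids(data, [0, 1, 2]) == (0, 2)

    def test_all_identical_ties_to_first_pair(self):
        data = np.ones((5, 3))
        assert select_initial_centroids(data, range(5)) == (0, 1)

    def test_matches_brute_force(self, rng):
        for _ in range(20):
            data = rng.random((12, 4))
            subset = sorted(rng.choice(12, size=7, replace=False).tolist())
            got = select_initial_centroids(data, subset)
            best = max(
                itertools.combinations(subset, 2),
                key=lambda p: (
                    np.linalg.norm(data[p[0]] - data[p[1]]),
                    (-p[0], -p[1]),
                ),
            )
            assert got == best

    def test_needs_two(self):
        with pytest.raises(ValueError):
            select_initial_centroids(np.ones((3, 2)), [1])


class TestBisect:
    def test_separated_clouds_recovered(self, rng):
        data, truth = blobs(rng, [np.zeros(3), np.full(3, 10.0)], 15)
        a, b = bisect(data, range(len(data)))
        groups = {frozenset(a.tolist()), frozenset(b.tolist())}
        assert groups == {frozenset(range(15)), frozenset(range(15, 30))}

    def test_pair_becomes_singletons(self):
        data = np.array([[0.0, 0.0], [5.0, 5.0]])
        a, b = bisect(data, [0, 1])
        assert sorted([a.tolist(), b.tolist()]) == [[0], [1]]

    def test_never_returns_empty_side(self):
        data = np.zeros((6, 2))  # fully degenerate input
        a, b = bisect(data, range(6))
        assert len(a) > 0 and len(b) > 0
        assert sorted(np.concatenate([a, b]).tolist()) == list(range(6))


class TestSplitSelection:
    def test_loose_cluster_wins(self, rng):
        tight = rng.normal(0, 0.01, size=(10, 2))
        loose = rng.normal(5, 2.0, size=(10, 2))
        data = np.vstack([tight, loose])
        pick = select_cluster_to_split(
            data, [list(range(10)), list(range(10, 20))]
        )
        assert pick == 1

    def test_variance_beats_size(self):
        """A huge coincident cluster has zero variance; the 2-point
        spread-out cluster must be chosen (the departure from
        largest-size splitting)."""
        data = np.vstack([np.zeros((1000, 2)), [[10.0, 0.0], [30.0, 0.0]]])
        pick = select_cluster_to_split(
            data, [list(range(1000)), [1000, 1001]]
        )
        assert pick == 1

    def test_variance_equals_direct_summation(self, rng):
        data = rng.random((15, 6))
        members = [2, 5, 7, 11]
        mu = data[members].mean(axis=0)
        direct = np.mean(
            [np.linalg.norm(data[i] - mu) ** 2 for i in members]
        )
        assert cluster_variance(data, members) == pytest.approx(direct)

    def test_singletons_never_selected(self):
        data = np.array([[0.0], [1.0], [2.0]])
        with pytest.raises(ValueError, match="cannot reach K"):
            select_cluster_to_split(data, [[0], [1], [2]])


class TestMbkm:
    def test_trivial_K(self, rng):
        data = rng.random((8, 4))
        _, flat = mbkm(data, 1)
        assert flat.K == 1 and (flat.assignment == 0).all()
        _, singles = mbkm(data, 8)
        assert singles.K == 8
        assert sorted(singles.assignment.tolist()) == list(range(8))

    def test_recovers_planted_families(self, four_families):
        data = featurize(four_families, k=3)
        _, flat = mbkm(data, 4)
        assert f_measure(four_families.labels, flat.assignment) == 1.0

    def test_tree_frontier_equals_flat_cut(self, rng):
        data, _ = blobs(rng, [np.zeros(2), [5, 5], [10, 0]], 8)
        tree, flat = mbkm(data, 3)
        leaves = tree.frontier()
        assert len(leaves) == 3
        for cid, leaf in enumerate(leaves):
            assert set(leaf.members) == set(np.flatnonzero(flat.assignment == cid))

    def test_partition_valid_at_every_K(self, rng):
        data = rng.random((20, 5))
        for K in range(1, 21):
            _, flat = mbkm(data, K)
            assert flat.K == K
            sizes = np.bincount(flat.assignment, minlength=K)
            assert (sizes >= 1).all()
            assert sizes.sum() == 20

    def test_deterministic_bitwise(self, rng):
        data = rng.random((30, 8))
        t1, f1 = mbkm(data, 5)
        t2, f2 = mbkm(data, 5)
        assert (f1.assignment == f2.assignment).all()
        assert to_newick(t1) == to_newick(t2)

    def test_K_out_of_range(self, rng):
        data = rng.random((5, 2))
        with pytest.raises(ValueError):
            mbkm(data, 0)
        with pytest.raises(ValueError):
            mbkm(data, 6)


class TestKmeans:
    def test_K_equals_N_zero_inertia(self, rng):
        data = rng.random((6, 3))
        flat = kmeans(data, 6, n_runs=3, seed=1)
        assert sorted(flat.assignment.tolist()) == list(range(6))

    def test_seed_reproducibility(self, rng):
        data = rng.random((25, 4))
        a = kmeans(data, 3, n_runs=5, seed=42)
        b = kmeans(data, 3, n_runs=5, seed=42)
        assert (a.assignment == b.assignment).all()
        for ra, rb in zip(a.per_run, b.per_run):
            assert (ra.assignment == rb.assignment).all()

    def test_well_separated_recovery_most_runs(self, rng):
        data, truth = blobs(rng, [np.zeros(2), [20, 0], [0, 20]], 10)
        flat = kmeans(data, 3, n_runs=10, seed=7)
        truth_labels = [str(t) for t in truth]
        per_run_f = [
            f_measure(truth_labels, run.assignment) for run in flat.per_run
        ]
        # random seeding lands two centroids in one blob in a sizeable
        # fraction of runs; a majority still recover, and the
        # best-inertia run always does
        assert sum(f == 1.0 for f in per_run_f) >= 5
        assert f_measure(truth_labels, flat.assignment) == 1.0


class TestBkm:
    def test_trivial_and_reproducible(self, rng):
        data = rng.random((12, 3))
        _, flat = bkm(data, 1, seed=0)
        assert flat.K == 1
        _, a = bkm(data, 4, seed=9)
        _, b = bkm(data, 4, seed=9)
        assert (a.assignment == b.assignment).all()

    def test_balanced_families_match_mbkm(self, four_families):
        data = featurize(four_families, k=3)
        _, fm = mbkm(data, 4)
        _, fb = bkm(data, 4, seed=2)
        assert same_partition(fm.assignment, fb.assignment)


class TestLinkage:
    def test_equidistant_chain_ties_break_low(self):
        # line 0-1-2-3: consecutive gaps all equal
        values = np.abs(np.subtract.outer(np.arange(4.0), np.arange(4.0)))
        m = DistanceMatrix(labels=list("abcd"), values=values)
        _, flat = linkage_cluster(m, "sl", 2)
        assert same_partition(flat.assignment, np.array([0, 0, 0, 1]))

    def test_two_blobs_all_methods_agree(self, rng):
        data, truth = blobs(rng, [np.zeros(2), [50, 50]], 6)
        d = np.linalg.norm(data[:, None] - data[None, :], axis=-1)
        m = DistanceMatrix(labels=[str(i) for i in range(12)], values=d)
        for method in ("sl", "cl", "al"):
            _, flat = linkage_cluster(m, method, 2)
            assert same_partition(flat.assignment, truth)

    @pytest.mark.parametrize("method,scipy_method", [
        ("sl", "single"), ("cl", "complete"), ("al", "average"),
    ])
    def test_matches_scipy_on_random_matrices(self, rng, method, scipy_method):
        """Tie-free random matrices: cut partitions equal scipy's."""
        for trial in range(10):
            n = int(rng.integers(4, 9))
            raw = rng.random((n, n)) * 10
            values = (raw + raw.T) / 2
            np.fill_diagonal(values, 0.0)
            m = DistanceMatrix(
                labels=[f"t{i}" for i in range(n)], values=values
            )
            Z = linkage(squareform(values), method=scipy_method)
            for K in range(1, n + 1):
                _, flat = linkage_cluster(m, method, K)
                expected = fcluster(Z, t=K, criterion="maxclust") - 1
                assert same_partition(flat.assignment, expected)


class TestUpgma:
    def test_three_taxon_hand_example(self):
        values = np.array([[0, 2, 6], [2, 0, 6], [6, 6, 0]], dtype=float)
        tree = upgma(DistanceMatrix(labels=["A", "B", "C"], values=values))
        assert to_newick(tree, with_heights=True) == "((A:1,B:1):2,C:3);"

    def test_equal_distances_tie_break(self):
        values = np.ones((4, 4)) - np.eye(4)
        tree = upgma(DistanceMatrix(labels=list("abcd"), values=values))
        assert tree.root.height == pytest.approx(0.5)
        newick = to_newick(tree, with_heights=True)
        assert newick.startswith("(((a:0.5,b:0.5)")

    def test_ultrametric_root_to_leaf_paths(self, rng):
        raw = rng.random((8, 8)) * 5 + 1
        values = (raw + raw.T) / 2
        np.fill_diagonal(values, 0.0)
        tree = upgma(
            DistanceMatrix(labels=[f"t{i}" for i in range(8)], values=values)
        )

        def depths(node, acc):
            if node.is_leaf:
                yield acc + node.height if node.height else acc
            else:
                for child in node.children:
                    yield from depths(child, acc + (node.height - child.height))

        paths = list(depths(tree.root, 0.0))
        assert np.allclose(paths, paths[0], atol=1e-9)


class TestNewick:
    def test_single_leaf(self):
        from dmkcluster.cluster import ClusterNode, ClusterTree

        tree = ClusterTree(
            root=ClusterNode(members=(0,)), method="mbkm", labels=["A"]
        )
        assert to_newick(tree) == "A;"

    def test_round_trip_preserves_topology(self, rng):
        import dendropy

        raw = rng.random((7, 7)) * 4
        values = (raw + raw.T) / 2
        np.fill_diagonal(values, 0.0)
        labels = [f"taxon{i}" for i in range(7)]
        tree = upgma(DistanceMatrix(labels=labels, values=values))
        newick = to_newick(tree, with_heights=True)
        parsed = dendropy.Tree.get(data=newick, schema="newick")
        assert sorted(t.label for t in parsed.taxon_namespace) == sorted(labels)
        # ultrametric heights survive serialization
        leaf_depths = [leaf.distance_from_root() for leaf in parsed.leaf_node_iter()]
        assert np.allclose(leaf_depths, leaf_depths[0], atol=1e-6)

    def test_mbkm_tree_emits_no_branch_lengths(self, rng):
        data = rng.random((6, 3))
        tree, _ = mbkm(data, 6)
        tree.labels = [f"s{i}" for i in range(6)]
        assert ":" not in to_newick(tree)


class TestScalingOfSeeding:
    def test_superlinear_but_subcubic(self, rng):
        """Max-pair seeding is quadratic in N: timing across a 4x range
        of N should scale clearly faster than linear, slower than cubic."""
        import time

        sizes = [200, 400, 800]
        times = []
        for n in sizes:
            data = rng.random((n, 16))
            best = np.inf
            for _ in range(3):
                t0 = time.perf_counter()
                select_initial_centroids(data, range(n))
                best = min(best, time.perf_counter() - t0)
            times.append(best)
        slope = np.polyfit(np.log(sizes), np.log(times), 1)[0]
        assert 1.0 < slope < 3.0
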