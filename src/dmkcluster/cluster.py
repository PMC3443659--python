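"""Clustering algorithms over sequence feature vectors.

The centre-piece is mBKM, a modified bisecting K-means that differs from
plain BKM in two ways:

* each bisection is seeded with the two maximally distant members of the
  cluster being split (instead of random points), which removes all
  randomness from the algorithm; and
* the cluster chosen for the next split is the one with the largest
  variance sigma_j = sum_i d^2(s_i, mu_j) / n_j (least compact), instead
  of the largest cluster, so unbalanced natural clusters are not torn
  apart merely for being big.

Baselines: Lloyd's K-means (KM), random-seeded bisecting K-means (BKM),
single/complete/average agglomerative linkage (SL/CL/AL) and UPGMA tree
building.  Every tie (equidistant assignment, equal maximal distance,
equal variance, equal merge distance) breaks toward the lowest index, so
all deterministic paths are exactly reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np
from scipy.spatial.distance import cdist

from .distance import DistanceMatrix

MAX_2MEANS_ITER = 100  # guards pathological oscillation; convergence is
#                        declared on unchanged assignments (float-safe)


# ---------------------------------------------------------------------------
# result containers


@dataclass
class ClusterNode:
    """Node of a binary cluster tree; ``members`` are sequence indices."""

    members: tuple[int, ...]
    children: tuple["ClusterNode", "ClusterNode"] | None = None
    split_variance: float | None = None
    height: float | None = None

    @property
    def is_leaf(self) -> bool:
        return self.children is None

    def leaves(self) -> Iterator["ClusterNode"]:
        if self.is_leaf:
            yield self
        else:
            for child in self.children:
                yield from child.leaves()


@dataclass
class ClusterTree:
    """Binary tree over sequence indices with optional taxon labels."""

    root: ClusterNode
    method: str
    labels: list[str] | None = None

    def frontier(self) -> list[ClusterNode]:
        """Current leaves, left to right."""
        return list(self.root.leaves())


@dataclass
class FlatClustering:
    """A partition: ``assignment[i]`` is the cluster id (0..K-1) of
    sequence i; every id has at least one member."""

    assignment: np.ndarray
    K: int
    per_run: list["FlatClustering"] = field(default_factory=list)

    def __post_init__(self) -> None:
        a = np.asarray(self.assignment, dtype=int)
        present = np.unique(a)
        if not np.array_equal(present, np.arange(self.K)):
            raise ValueError(
                f"assignment must use every id in 0..{self.K - 1}"
            )
        self.assignment = a

    def clusters(self) -> list[np.ndarray]:
        return [np.flatnonzero(self.assignment == j) for j in range(self.K)]


def _tree_cut_to_flat(tree: ClusterTree, n: int) -> FlatClustering:
    leaves = tree.frontier()
    assignment = np.empty(n, dtype=int)
    for cid, leaf in enumerate(leaves):
        assignment[list(leaf.members)] = cid
    return FlatClustering(assignment=assignment, K=len(leaves))


# ---------------------------------------------------------------------------
# mBKM building blocks


def _pairwise(data: np.ndarray, metric: str) -> np.ndarray:
    scipy_metric = {"dmk": "euclidean", "euclidean": "euclidean",
                    "ktuple": "cityblock", "l1": "cityblock"}[metric]
    return cdist(data, data, metric=scipy_metric)


def select_initial_centroids(
    data: np.ndarray, subset: Sequence[int], metric: str = "euclidean"
) -> tuple[int, int]:
    """The two maximally distant members of ``subset`` (avoids seeding a
    bisection with adjacent elements); ties break to the smallest (i, j)."""
    idx = np.asarray(sorted(subset), dtype=int)
    if idx.size < 2:
        raise ValueError("need at least 2 members to seed a bisection")
    d = _pairwise(data[idx], metric)
    iu = np.triu_indices(idx.size, k=1)
    best = np.argmax(d[iu])  # first max in row-major order = lexicographic
    return int(idx[iu[0][best]]), int(idx[iu[1][best]])


def _two_means(
    data: np.ndarray,
    subset: np.ndarray,
    c0: np.ndarray,
    c1: np.ndarray,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Lloyd iterations for exactly two centroids on ``subset``.

    Returns (members0, members1, within-cluster sum of squares).  If an
    iteration empties one side, the point farthest from the surviving
    centroid is moved over, so both sides are always non-empty.
    """
    points = data[subset]
    prev = None
    for _ in range(MAX_2MEANS_ITER):
        d = cdist(points, np.vstack([c0, c1]))
        assign = np.argmin(d, axis=1)  # tie -> centroid 0 (lowest index)
        for empty, full in ((0, 1), (1, 0)):
            if not (assign == empty).any():
                far = int(np.argmax(d[:, full]))
                assign[far] = empty
        if prev is not None and np.array_equal(assign, prev):
            break
        prev = assign
        c0 = points[assign == 0].mean(axis=0)
        c1 = points[assign == 1].mean(axis=0)
    d = cdist(points, np.vstack([c0, c1]))
    wcss = float((d[np.arange(len(points)), assign] ** 2).sum())
    return subset[assign == 0], subset[assign == 1], wcss


def bisect(
    data: np.ndarray, subset: Sequence[int], metric: str = "euclidean"
) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic 2-means split seeded by the maximally distant pair.

    Assignment and centroid updates use Euclidean distance in feature
    space; the seeding pair may be chosen under the configured metric.
    """
    subset = np.asarray(sorted(subset), dtype=int)
    i, j = select_initial_centroids(data, subset, metric)
    a, b, _ = _two_means(data, subset, data[i].astype(float), data[j].astype(float))
    return a, b


def cluster_variance(data: np.ndarray, members: Sequence[int]) -> float:
    """sigma_j = mean squared Euclidean distance of members to their
    centroid; the compactness score used to pick the next split."""
    pts = data[np.asarray(list(members), dtype=int)]
    mu = pts.mean(axis=0)
    return float(((pts - mu) ** 2).sum(axis=1).mean())


def select_cluster_to_split(
    data: np.ndarray, clusters: Sequence[Sequence[int]]
) -> int:
    """Index of the splittable (size >= 2) cluster with maximal variance;
    ties break to the lowest index."""
    best, best_var = -1, -np.inf
    for idx, members in enumerate(clusters):
        if len(members) < 2:
            continue
        var = cluster_variance(data, members)
        if var > best_var:
            best, best_var = idx, var
    if best < 0:
        raise ValueError("cannot reach K: no cluster with >= 2 members")
    return best


# ---------------------------------------------------------------------------
# top-level clusterers


def _check_K(K: int, n: int) -> None:
    if not 1 <= K <= n:
        raise ValueError(f"K must be in 1..{n}, got {K}")


def mbkm(
    data: np.ndarray,
    K: int,
    metric: str = "euclidean",
    labels: list[str] | None = None,
) -> tuple[ClusterTree, FlatClustering]:
    """Modified bisecting K-means; fully deterministic.

    Starting from one cluster holding every sequence, repeatedly split
    the highest-variance cluster with a max-distance-seeded 2-means until
    K clusters exist.  Returns the binary split tree (frontier = the K
    clusters) and the flat K-partition.
    """
    data = np.asarray(data, dtype=float)
    n = len(data)
    _check_K(K, n)
    root = ClusterNode(members=tuple(range(n)))
    frontier = [root]
    while len(frontier) < K:
        pick = select_cluster_to_split(
            data, [node.members for node in frontier]
        )
        node = frontier[pick]
        node.split_variance = cluster_variance(data, node.members)
        left, right = bisect(data, node.members, metric)
        node.children = (
            ClusterNode(members=tuple(int(i) for i in left)),
            ClusterNode(members=tuple(int(i) for i in right)),
        )
        frontier[pick : pick + 1] = list(node.children)
    tree = ClusterTree(root=root, method="mbkm", labels=labels)
    return tree, _tree_cut_to_flat(tree, n)


def kmeans(
    data: np.ndarray,
    K: int,
    n_runs: int = 10,
    seed: int = 0,
    max_iter: int = 300,
) -> FlatClustering:
    """Lloyd's K-means with uniform-random distinct data points as the
    initial centroids; returns the best-inertia run, with every run's
    partition kept in ``per_run`` for average-performance reporting."""
    data = np.asarray(data, dtype=float)
    n = len(data)
    _check_K(K, n)
    rng = np.random.default_rng(seed)
    runs: list[tuple[float, FlatClustering]] = []
    for _ in range(n_runs):
        centroids = data[rng.choice(n, size=K, replace=False)].astype(float)
        prev = None
        for _ in range(max_iter):
            d = cdist(data, centroids)
            assign = np.argmin(d, axis=1)
            for j in range(K):  # empty-cluster repair
                if not (assign == j).any():
                    far = int(np.argmax(d[np.arange(n), assign]))
                    assign[far] = j
                    d[far, :] = 0.0
            if prev is not None and np.array_equal(assign, prev):
                break
            prev = assign
            centroids = np.vstack(
                [data[assign == j].mean(axis=0) for j in range(K)]
            )
        inertia = float(
            ((data - centroids[assign]) ** 2).sum()
        )
        ids = {c: i for i, c in enumerate(dict.fromkeys(assign.tolist()))}
        relabelled = np.array([ids[c] for c in assign.tolist()])
        runs.append((inertia, FlatClustering(assignment=relabelled, K=K)))
    best = min(range(n_runs), key=lambda r: runs[r][0])
    result = runs[best][1]
    result.per_run = [fc for _, fc in runs]
    return result


def bkm(
    data: np.ndarray,
    K: int,
    n_trials_per_split: int = 5,
    seed: int = 0,
    labels: list[str] | None = None,
) -> tuple[ClusterTree, FlatClustering]:
    """Plain bisecting K-means baseline: split the largest cluster,
    seeding each 2-means with random member pairs, best of
    ``n_trials_per_split`` restarts by within-cluster sum of squares."""
    data = np.asarray(data, dtype=float)
    n = len(data)
    _check_K(K, n)
    rng = np.random.default_rng(seed)
    root = ClusterNode(members=tuple(range(n)))
    frontier = [root]
    while len(frontier) < K:
        sizes = [len(nd.members) if len(nd.members) >= 2 else -1 for nd in frontier]
        pick = int(np.argmax(sizes))
        if sizes[pick] < 2:
            raise ValueError("cannot reach K: no cluster with >= 2 members")
        node = frontier[pick]
        subset = np.asarray(node.members, dtype=int)
        best: tuple[np.ndarray, np.ndarray] | None = None
        best_wcss = np.inf
        for _ in range(n_trials_per_split):
            i, j = rng.choice(len(subset), size=2, replace=False)
            a, b, wcss = _two_means(
                data, subset, data[subset[i]].astype(float),
                data[subset[j]].astype(float),
            )
            if wcss < best_wcss:
                best, best_wcss = (a, b), wcss
        node.children = (
            ClusterNode(members=tuple(int(i) for i in best[0])),
            ClusterNode(members=tuple(int(i) for i in best[1])),
        )
        frontier[pick : pick + 1] = list(node.children)
    tree = ClusterTree(root=root, method="bkm", labels=labels)
    return tree, _tree_cut_to_flat(tree, n)


# ---------------------------------------------------------------------------
# agglomerative methods (distance-matrix based)

_LINKAGES = ("sl", "cl", "al")


def _agglomerate(matrix: DistanceMatrix, method: str) -> ClusterNode:
    """Bottom-up merging with deterministic lowest-index tie-breaks.

    Cluster-pair distances follow Lance-Williams updates: min (sl),
    max (cl), or the size-weighted mean of all cross-pair distances
    (al/upgma).  Merge heights are recorded as half the merge distance.
    """
    n = matrix.n
    nodes: list[ClusterNode] = [
        ClusterNode(members=(i,), height=0.0) for i in range(n)
    ]
    d = matrix.values.astype(float).copy()
    active = list(range(n))
    while len(active) > 1:
        best_pair, best_d = None, np.inf
        for ai in range(len(active)):
            for aj in range(ai + 1, len(active)):
                dij = d[active[ai], active[aj]]
                if dij < best_d:
                    best_pair, best_d = (ai, aj), dij
        ai, aj = best_pair
        i, j = active[ai], active[aj]
        merged = ClusterNode(
            members=tuple(sorted(nodes[i].members + nodes[j].members)),
            children=(nodes[i], nodes[j]),
            height=best_d / 2.0,
        )
        ni, nj = len(nodes[i].members), len(nodes[j].members)
        for other in active:
            if other in (i, j):
                continue
            if method == "sl":
                new = min(d[i, other], d[j, other])
            elif method == "cl":
                new = max(d[i, other], d[j, other])
            else:  # al / upgma: proportional (size-weighted) averaging
                new = (ni * d[i, other] + nj * d[j, other]) / (ni + nj)
            d[i, other] = d[other, i] = new
        nodes[i] = merged
        active.pop(aj)
    return nodes[active[0]]


def linkage_cluster(
    matrix: DistanceMatrix, method: str, K: int
) -> tuple[ClusterTree, FlatClustering]:
    """Single/complete/average agglomerative clustering cut at K clusters.

    The cut removes the K-1 highest merges (the last K-1 performed),
    i.e. descends from the root until K subtrees remain, splitting the
    highest node first.
    """
    if method not in _LINKAGES:
        raise ValueError(f"method must be one of {_LINKAGES}")
    n = matrix.n
    _check_K(K, n)
    root = _agglomerate(matrix, method)
    frontier = [root]
    while len(frontier) < K:
        # split the frontier node with the greatest merge height; ties by
        # position (lowest first)
        heights = [
            nd.height if not nd.is_leaf else -np.inf for nd in frontier
        ]
        pick = int(np.argmax(heights))
        node = frontier[pick]
        frontier[pick : pick + 1] = list(node.children)
    tree = ClusterTree(root=root, method=method, labels=list(matrix.labels))
    assignment = np.empty(n, dtype=int)
    for cid, nd in enumerate(frontier):
        assignment[list(nd.members)] = cid
    return tree, FlatClustering(assignment=assignment, K=K)


def upgma(matrix: DistanceMatrix) -> ClusterTree:
    """UPGMA tree: size-weighted average linkage with node heights equal
    to half the merge distance; the result is ultrametric."""
    if matrix.n < 2:
        raise ValueError("need at least 2 taxa")
    root = _agglomerate(matrix, "al")
    return ClusterTree(root=root, method="upgma", labels=list(matrix.labels))


# ---------------------------------------------------------------------------
# Newick export


def _escape(name: str) -> str:
    if any(c in name for c in " ()[]:;,'"):
        return "'" + name.replace("'", "''") + "'"
    return name


def to_newick(tree: ClusterTree, with_heights: bool = False) -> str:
    """Serialize a cluster tree as Newick.

    Trees from the bisecting algorithms carry no heights and emit bare
    topology; UPGMA/agglomerative trees emit branch lengths derived from
    node heights when ``with_heights``.  A frontier leaf holding several
    sequences becomes an unresolved clade of its members.
    """
    labels = tree.labels

    def name_of(i: int) -> str:
        return _escape(labels[i]) if labels else f"seq{i}"

    def render(node: ClusterNode, parent_height: float | None) -> str:
        if node.is_leaf:
            if len(node.members) == 1:
                body = name_of(node.members[0])
            else:
                body = "(" + ",".join(name_of(i) for i in node.members) + ")"
            h = node.height or 0.0
        else:
            body = (
                "("
                + ",".join(render(c, node.height) for c in node.children)
                + ")"
            )
            h = node.height
        if with_heights and parent_height is not None and h is not None:
            body += f":{parent_height - h:g}"
        return body

    return render(tree.root, None) + ";"
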