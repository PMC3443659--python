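"""Pairwise alignment-free distances and labelled distance matrices.

DMk is the Euclidean (L2) distance between two sequences' per-tuple
positional entropy vectors; the baseline k-tuple distance is the L1
distance between raw overlapping count vectors.  Both are norms of
vector differences, so all metric axioms hold at the vector level.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .features import EntropyFeatureVector, FrequencyVector

_PHYLIP_NAME_WIDTH = 10


@dataclass
class DistanceMatrix:
    """Symmetric zero-diagonal matrix of pairwise sequence distances,
    labelled in the order of the SequenceSet it was built from."""

    labels: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.labels)
        v = np.asarray(self.values, dtype=float)
        if v.shape != (n, n):
            raise ValueError(f"matrix shape {v.shape} != ({n}, {n})")
        if not np.isfinite(v).all():
            raise ValueError("non-finite distances")
        if not np.allclose(v, v.T):
            raise ValueError("matrix not symmetric")
        if not np.allclose(np.diag(v), 0.0):
            raise ValueError("nonzero diagonal")
        self.values = v

    @property
    def n(self) -> int:
        return len(self.labels)

    def __getitem__(self, pair: tuple[str, str]) -> float:
        i = self.labels.index(pair[0])
        j = self.labels.index(pair[1])
        return float(self.values[i, j])


def _check_compatible(x, y) -> None:
    if x.k != y.k:
        raise ValueError(f"mismatched k: {x.k} != {y.k}")


def dmk_distance(x: EntropyFeatureVector, y: EntropyFeatureVector) -> float:
    """Euclidean distance between two positional-entropy vectors."""
    _check_compatible(x, y)
    return float(np.linalg.norm(x.values - y.values))


def ktuple_distance(x: FrequencyVector, y: FrequencyVector) -> float:
    """Sum of absolute count differences over all 4^k tuples (L1)."""
    _check_compatible(x, y)
    return float(np.abs(x.counts.astype(np.int64) - y.counts.astype(np.int64)).sum())


def distance_matrix(
    vectors: list[EntropyFeatureVector] | list[FrequencyVector] | np.ndarray,
    metric: str = "dmk",
    labels: list[str] | None = None,
) -> DistanceMatrix:
    """All-pairs distances for a homogeneous list of feature vectors.

    ``metric="dmk"`` is Euclidean on entropy vectors; ``metric="ktuple"``
    is L1 ("cityblock") on count vectors.  A raw (N, 4^k) array is also
    accepted (rows in label order).
    """
    if metric not in ("dmk", "ktuple"):
        raise ValueError(f"unknown metric {metric!r}")
    if isinstance(vectors, np.ndarray):
        data = np.asarray(vectors, dtype=float)
        if labels is None:
            labels = [str(i) for i in range(len(data))]
    else:
        if len(vectors) < 2:
            raise ValueError("need at least 2 vectors")
        kinds = {type(v) for v in vectors}
        ks = {v.k for v in vectors}
        if len(kinds) > 1 or len(ks) > 1:
            raise ValueError("heterogeneous feature vectors")
        expected = EntropyFeatureVector if metric == "dmk" else FrequencyVector
        if kinds != {expected}:
            raise ValueError(
                f"metric {metric!r} expects {expected.__name__} inputs"
            )
        rows = [
            v.values if isinstance(v, EntropyFeatureVector) else v.counts
            for v in vectors
        ]
        data = np.asarray(rows, dtype=float)
        if labels is None:
            labels = [
                v.sequence_id or str(i) for i, v in enumerate(vectors)
            ]
    scipy_metric = "euclidean" if metric == "dmk" else "cityblock"
    condensed = pdist(data, metric=scipy_metric)
    return DistanceMatrix(labels=list(labels), values=squareform(condensed))


def pairwise_from_array(data: np.ndarray, metric: str = "dmk") -> np.ndarray:
    """Square distance array from an (N, d) feature matrix (no labels)."""
    scipy_metric = "euclidean" if metric == "dmk" else "cityblock"
    return squareform(pdist(np.asarray(data, dtype=float), metric=scipy_metric))


def write_phylip(matrix: DistanceMatrix, path: str | Path, relaxed: bool = False) -> None:
    """Write a square PHYLIP distance matrix.

    Classic dialect pads/truncates names to 10 characters; ``relaxed``
    keeps full names followed by two spaces (accepted by modern tools).
    """
    lines = [f"{matrix.n:5d}"]
    for name, row in zip(matrix.labels, matrix.values):
        if relaxed:
            field = f"{name}  "
        else:
            field = f"{name[:_PHYLIP_NAME_WIDTH]:<{_PHYLIP_NAME_WIDTH}}"
        lines.append(field + " ".join(f"{v:.6f}" for v in row))
    Path(path).write_text("\n".join(lines) + "\n")


def read_phylip(path: str | Path) -> DistanceMatrix:
    """Read a square PHYLIP distance matrix (classic or relaxed names)."""
    lines = [ln for ln in Path(path).read_text().splitlines() if ln.strip()]
    n = int(lines[0].split()[0])
    if len(lines) - 1 != n:
        raise ValueError(f"expected {n} taxon rows, found {len(lines) - 1}")
    labels, rows = [], []
    for line in lines[1:]:
        parts = line.split()
        if len(parts) == n + 1:
            name, values = parts[0], parts[1:]
        else:
            # classic dialect: name is a fixed 10-character field that may
            # abut the first value with no separator
            name = line[:_PHYLIP_NAME_WIDTH].strip()
            values = line[_PHYLIP_NAME_WIDTH:].split()
        if not name or len(values) != n:
            raise ValueError(f"row has {len(values)} values, expected {n}")
        labels.append(name)
        rows.append([float(v) for v in values])
    values = np.asarray(rows)
    # rounding in text output can leave tiny asymmetries; resymmetrize
    values = (values + values.T) / 2.0
    np.fill_diagonal(values, 0.0)
    return DistanceMatrix(labels=labels, values=values)


def write_tsv(matrix: DistanceMatrix, path: str | Path) -> None:
    """TSV alternative with full IDs (header row + row labels)."""
    lines = ["\t".join(["id"] + matrix.labels)]
    for name, row in zip(matrix.labels, matrix.values):
        lines.append(name + "\t" + "\t".join(f"{v:.12g}" for v in row))
    Path(path).write_text("\n".join(lines) + "\n")


def read_tsv(path: str | Path) -> DistanceMatrix:
    lines = Path(path).read_text().splitlines()
    labels = lines[0].split("\t")[1:]
    rows = []
    for line in lines[1:]:
        parts = line.split("\t")
        rows.append([float(v) for v in parts[1:]])
    return DistanceMatrix(labels=labels, values=np.asarray(rows))
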