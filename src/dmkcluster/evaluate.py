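"""Clustering quality scored against known class labels by F-measure.

For class i and cluster j, precision = n_ij / n_j and recall = n_ij / n_i
(n_ij = members of class i landing in cluster j); F(i, j) is their
harmonic mean, with the 0/0 case defined as 0.  The overall score weights
each class by its size and takes the best-matching cluster:

    F = sum_i (n_i / N) * max_j F(i, j),   0 <= F <= 1,

reaching 1 exactly when the clustering is a relabelling of the classes.
Note the score is asymmetric in classes vs clusters: it penalizes
splitting a class across clusters more gently than merging classes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np

logger = logging.getLogger(__name__)


@dataclass
class ContingencyTable:
    """Class-by-cluster count matrix with consistent marginals."""

    classes: list[str]
    clusters: list[int]
    n_ij: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.n_ij, dtype=int)
        if m.shape != (len(self.classes), len(self.clusters)):
            raise ValueError("n_ij shape inconsistent with labels")
        if (m < 0).any():
            raise ValueError("negative counts")
        if m.sum() == 0:
            raise ValueError("empty contingency table")
        self.n_ij = m

    @property
    def n_i(self) -> np.ndarray:
        return self.n_ij.sum(axis=1)

    @property
    def n_j(self) -> np.ndarray:
        return self.n_ij.sum(axis=0)

    @property
    def N(self) -> int:
        return int(self.n_ij.sum())


def contingency(
    true_labels: Sequence[str], assignment: Sequence[int]
) -> ContingencyTable:
    """Build the class-vs-cluster table from parallel label/assignment
    lists.  Items with a ``None`` label are excluded (logged)."""
    if len(true_labels) != len(assignment):
        raise ValueError("labels and assignment lengths differ")
    pairs = [
        (lab, cid)
        for lab, cid in zip(true_labels, assignment)
        if lab is not None
    ]
    dropped = len(true_labels) - len(pairs)
    if dropped:
        logger.info("evaluation: %d unlabelled item(s) excluded", dropped)
    if not pairs:
        raise ValueError("no labelled items to evaluate")
    classes = sorted({lab for lab, _ in pairs})
    clusters = sorted({cid for _, cid in pairs})
    cls_idx = {c: i for i, c in enumerate(classes)}
    clu_idx = {c: j for j, c in enumerate(clusters)}
    m = np.zeros((len(classes), len(clusters)), dtype=int)
    for lab, cid in pairs:
        m[cls_idx[lab], clu_idx[cid]] += 1
    return ContingencyTable(classes=classes, clusters=clusters, n_ij=m)


def pair_f(table: ContingencyTable, i: int, j: int) -> float:
    """F(i, j): harmonic mean of precision n_ij/n_j and recall n_ij/n_i;
    0 when class i and cluster j do not overlap."""
    if not 0 <= i < len(table.classes):
        raise IndexError(f"unknown class index {i}")
    if not 0 <= j < len(table.clusters):
        raise IndexError(f"unknown cluster index {j}")
    nij = table.n_ij[i, j]
    if nij == 0:
        return 0.0
    precision = nij / table.n_j[j]
    recall = nij / table.n_i[i]
    return float(2 * precision * recall / (precision + recall))


def overall_f(table: ContingencyTable) -> float:
    """Class-size-weighted best-cluster F over the whole partition."""
    total = 0.0
    for i, ni in enumerate(table.n_i):
        if ni == 0:
            continue
        best = max(pair_f(table, i, j) for j in range(len(table.clusters)))
        total += (ni / table.N) * best
    return total


def f_measure(true_labels: Sequence[str], assignment: Sequence[int]) -> float:
    """Convenience wrapper: contingency + overall F in one call."""
    return overall_f(contingency(true_labels, assignment))
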