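"""k-tuple feature extraction for DNA sequences.

Two representations are produced from overlapping (step-1) k-tuple scans:

* the positional-entropy vector (the DMk representation): for each of the
  4^k tuples, the inter-occurrence gaps are turned into reciprocals
  ``alpha_r = 1/(p_r - p_{r-1})`` (1-based positions, ``p_0 = 0``), their
  running sums ``beta_j`` are normalized into a discrete probability
  distribution q, and the coordinate is the Shannon entropy
  ``H = -sum(q log2 q)`` in bits.  A tuple occurring 0 or 1 times
  contributes 0 (one occurrence carries no positional-order information).

* the plain frequency (count) vector used by the baseline k-tuple
  distance, which discards all positional information.

Coordinates are indexed by the lexicographic tuple order A < C < G < T,
frozen so serialized vectors are reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product
from pathlib import Path
from typing import Sequence

import numpy as np

from .seqio import ALPHABET, SequenceRecord, SequenceSet

_CODE = np.full(128, -1, dtype=np.int64)
for _i, _ch in enumerate(ALPHABET):
    _CODE[ord(_ch)] = _i

K_MAX = 8  # 4^8 = 65536 coordinates; memory guard


@dataclass(frozen=True)
class TupleAlphabet:
    """The ordered set of all 4^k tuples; a tuple's index is its fixed
    coordinate in every feature vector."""

    k: int

    def __post_init__(self) -> None:
        if not 1 <= self.k <= K_MAX:
            raise ValueError(f"k must be in 1..{K_MAX}, got {self.k}")

    @property
    def size(self) -> int:
        return 4**self.k

    @property
    def tuples(self) -> list[str]:
        return ["".join(p) for p in product(ALPHABET, repeat=self.k)]

    def index(self, tup: str) -> int:
        if len(tup) != self.k or any(c not in ALPHABET for c in tup):
            raise ValueError(f"not a {self.k}-tuple over ACGT: {tup!r}")
        idx = 0
        for ch in tup:
            idx = idx * 4 + ALPHABET.index(ch)
        return idx


@dataclass(frozen=True)
class OccurrenceProfile:
    """All 1-based start positions of one tuple in one sequence
    (overlapping sliding-window scan, step 1)."""

    tuple: str
    positions: tuple[int, ...]

    @property
    def m(self) -> int:
        return len(self.positions)


@dataclass(frozen=True)
class EntropyFeatureVector:
    """The 4^k-dimensional per-tuple positional entropy vector (bits)."""

    k: int
    values: np.ndarray
    sequence_id: str = ""

    def __post_init__(self) -> None:
        if self.values.shape != (4**self.k,):
            raise ValueError("values length must be 4^k")


@dataclass(frozen=True)
class FrequencyVector:
    """The 4^k-dimensional overlapping k-tuple count vector."""

    k: int
    counts: np.ndarray
    sequence_id: str = ""

    def __post_init__(self) -> None:
        if self.counts.shape != (4**self.k,):
            raise ValueError("counts length must be 4^k")


def _encode(residues: str) -> np.ndarray:
    codes = _CODE[np.frombuffer(residues.encode("ascii"), dtype=np.uint8)]
    if (codes < 0).any():
        raise ValueError("residues contain non-ACGT characters")
    return codes


def _kmer_ids(residues: str, k: int) -> np.ndarray:
    """Integer id of every overlapping k-mer (lexicographic ACGT base-4)."""
    codes = _encode(residues)
    n = len(codes) - k + 1
    if n < 1:
        raise ValueError(
            f"sequence shorter than k ({len(codes)} < {k})"
        )
    ids = np.zeros(n, dtype=np.int64)
    for offset in range(k):
        ids = ids * 4 + codes[offset : offset + n]
    return ids


def occurrence_profile(residues: str, tup: str) -> OccurrenceProfile:
    """Locate every overlapping occurrence of ``tup`` (1-based starts)."""
    k = len(tup)
    alphabet = TupleAlphabet(k)
    ids = _kmer_ids(residues, k)
    target = alphabet.index(tup)
    positions = tuple(int(p) + 1 for p in np.flatnonzero(ids == target))
    return OccurrenceProfile(tuple=tup, positions=positions)


def alpha_series(profile: OccurrenceProfile) -> np.ndarray:
    """Reciprocal gaps alpha_r = 1/(p_r - p_{r-1}), p_0 = 0.

    Each alpha_r lies in (0, 1]; alpha_1 = 1/p_1 ties the series to the
    absolute location of the first occurrence.
    """
    if profile.m == 0:
        raise ValueError(f"tuple {profile.tuple!r} does not occur")
    pos = np.asarray(profile.positions, dtype=float)
    return 1.0 / np.diff(pos, prepend=0.0)


def beta_series(alphas: Sequence[float] | np.ndarray) -> np.ndarray:
    """Strictly increasing partial sums beta_j = sum(alpha_1..alpha_j)."""
    alphas = np.asarray(alphas, dtype=float)
    if alphas.size == 0:
        raise ValueError("empty alpha series")
    if (alphas <= 0).any():
        raise ValueError("alpha values must be positive")
    return np.cumsum(alphas)


def tuple_entropy(betas: Sequence[float] | np.ndarray) -> float:
    """Shannon entropy (bits) of the normalized beta series.

    q_i = beta_i / sum(beta); H = -sum(q_i log2 q_i).  A single
    occurrence gives the degenerate distribution q = (1,), hence H = 0.
    """
    betas = np.asarray(betas, dtype=float)
    if betas.size == 0:
        raise ValueError("empty beta series")
    q = betas / betas.sum()
    return float(-(q * np.log2(q)).sum())


def entropy_vector(
    record: SequenceRecord | str, alphabet: TupleAlphabet
) -> EntropyFeatureVector:
    """Full 4^k positional-entropy vector of one sequence.

    Coordinates of absent tuples are 0 by convention, keeping the vector
    a fixed-length index of the sequence.
    """
    residues, seq_id = _residues_and_id(record)
    ids = _kmer_ids(residues, alphabet.k)
    values = np.zeros(alphabet.size)
    # stable argsort groups equal tuple ids while keeping positions ordered
    order = np.argsort(ids, kind="stable")
    sorted_ids = ids[order]
    bounds = np.flatnonzero(np.diff(sorted_ids)) + 1
    group_ids = sorted_ids[np.concatenate(([0], bounds))]
    for grp, tid in zip(np.split(order, bounds), group_ids):
        pos = grp.astype(float) + 1.0  # 1-based
        alphas = 1.0 / np.diff(pos, prepend=0.0)
        betas = np.cumsum(alphas)
        q = betas / betas.sum()
        values[tid] = -(q * np.log2(q)).sum()
    return EntropyFeatureVector(k=alphabet.k, values=values, sequence_id=seq_id)


def frequency_vector(
    record: SequenceRecord | str, alphabet: TupleAlphabet
) -> FrequencyVector:
    """Overlapping k-tuple counts; coordinates sum to s - k + 1."""
    residues, seq_id = _residues_and_id(record)
    ids = _kmer_ids(residues, alphabet.k)
    counts = np.bincount(ids, minlength=alphabet.size)
    return FrequencyVector(k=alphabet.k, counts=counts, sequence_id=seq_id)


def _residues_and_id(record: SequenceRecord | str) -> tuple[str, str]:
    if isinstance(record, SequenceRecord):
        return record.residues, record.id
    return record, ""


def featurize(
    seqs: SequenceSet, k: int = 3, kind: str = "entropy"
) -> np.ndarray:
    """Stack feature vectors for a whole set into an (N, 4^k) float array.

    ``kind`` selects the representation: "entropy" (DMk) or "frequency"
    (baseline counts, returned as floats so both feed the same clusterers).
    """
    alphabet = TupleAlphabet(k)
    if kind == "entropy":
        rows = [entropy_vector(r, alphabet).values for r in seqs]
    elif kind == "frequency":
        rows = [frequency_vector(r, alphabet).counts.astype(float) for r in seqs]
    else:
        raise ValueError(f"unknown feature kind {kind!r}")
    return np.vstack(rows)


def write_vectors_tsv(
    seqs: SequenceSet, matrix: np.ndarray, k: int, path: str | Path
) -> None:
    """Serialize an (N, 4^k) feature matrix as TSV with a tuple header."""
    alphabet = TupleAlphabet(k)
    header = "id\t" + "\t".join(alphabet.tuples)
    lines = [header]
    for rec, row in zip(seqs, matrix):
        lines.append(rec.id + "\t" + "\t".join(f"{v:.12g}" for v in row))
    Path(path).write_text("\n".join(lines) + "\n")


def read_vectors_tsv(path: str | Path) -> tuple[list[str], np.ndarray, int]:
    """Inverse of :func:`write_vectors_tsv`; returns (ids, matrix, k)."""
    lines = Path(path).read_text().splitlines()
    header = lines[0].split("\t")
    n_tuples = len(header) - 1
    k = int(round(np.log(n_tuples) / np.log(4)))
    if 4**k != n_tuples:
        raise ValueError(f"header has {n_tuples} tuple columns; not a power of 4")
    ids, rows = [], []
    for line in lines[1:]:
        parts = line.split("\t")
        ids.append(parts[0])
        rows.append([float(v) for v in parts[1:]])
    return ids, np.asarray(rows), k
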