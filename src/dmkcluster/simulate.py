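"""Synthetic labelled gene families for testing and benchmarking.

Each family descends from an independent uniform-random ACGT ancestor;
members are derived by per-site substitution (uniform over the three
alternative bases) and, optionally, per-site indel events with
geometric lengths.  This emulates the structure the clustering targets
— several families of related sequences, possibly of heterogeneous
lengths and unequal sizes — while providing exact ground-truth labels.
It does not model codon structure, rate heterogeneity, or shared
phylogeny within a family (every member is an independent draw from the
ancestor), so recovery here is easier than on deeply diverged real
families.

Members are emitted in a seeded shuffle so downstream clustering never
benefits from input-order artifacts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .seqio import ALPHABET, SequenceRecord, SequenceSet

_BASES = np.frombuffer(ALPHABET.encode(), dtype=np.uint8)


@dataclass(frozen=True)
class FamilyModel:
    """Parameters of one synthetic dataset.

    substitution_rate/indel_rate are per-site event probabilities in
    [0, 1); indel lengths are geometric, capped at ``max_indel_len``.
    """

    n_families: int
    seqs_per_family: tuple[int, ...]
    ancestor_lengths: tuple[int, ...]
    substitution_rate: float = 0.02
    indel_rate: float = 0.0
    max_indel_len: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_families < 1:
            raise ValueError("need at least one family")
        if len(self.seqs_per_family) != self.n_families:
            raise ValueError("seqs_per_family length != n_families")
        if len(self.ancestor_lengths) != self.n_families:
            raise ValueError("ancestor_lengths length != n_families")
        if any(s < 1 for s in self.seqs_per_family):
            raise ValueError("family sizes must be >= 1")
        if any(l < 1 for l in self.ancestor_lengths):
            raise ValueError("ancestor lengths must be >= 1")
        for name in ("substitution_rate", "indel_rate"):
            rate = getattr(self, name)
            if not 0.0 <= rate < 1.0:
                raise ValueError(f"{name} must be in [0, 1)")
        if self.max_indel_len < 1:
            raise ValueError("max_indel_len must be >= 1")


def _random_seq(rng: np.random.Generator, length: int) -> np.ndarray:
    return _BASES[rng.integers(0, 4, size=length)]


def _mutate(
    rng: np.random.Generator, ancestor: np.ndarray, model: FamilyModel
) -> str:
    seq = ancestor.copy()
    if model.substitution_rate > 0:
        hits = np.flatnonzero(rng.random(seq.size) < model.substitution_rate)
        if hits.size:
            # uniform over the 3 alternatives: shift by 1..3 in base order
            cur = np.searchsorted(_BASES, seq[hits])
            seq[hits] = _BASES[(cur + rng.integers(1, 4, size=hits.size)) % 4]
    if model.indel_rate > 0:
        out: list[np.ndarray] = []
        cursor = 0
        events = np.flatnonzero(rng.random(seq.size) < model.indel_rate)
        for pos in events:
            if pos < cursor:
                continue
            length = min(int(rng.geometric(0.5)), model.max_indel_len)
            if rng.random() < 0.5:  # deletion
                out.append(seq[cursor:pos])
                cursor = pos + length
            else:  # insertion
                out.append(seq[cursor:pos])
                out.append(_random_seq(rng, length))
                cursor = pos
        out.append(seq[cursor:])
        seq = np.concatenate(out) if out else seq
        if seq.size == 0:
            seq = _random_seq(rng, 1)
    return seq.tobytes().decode("ascii")


def generate_families(model: FamilyModel) -> SequenceSet:
    """Draw a labelled SequenceSet from the family model.

    Fully reproducible: the same model (including seed) yields
    byte-identical output.
    """
    rng = np.random.default_rng(model.seed)
    records: list[SequenceRecord] = []
    for fam in range(model.n_families):
        ancestor = _random_seq(rng, model.ancestor_lengths[fam])
        label = f"family{fam}"
        for member in range(model.seqs_per_family[fam]):
            residues = _mutate(rng, ancestor, model)
            records.append(
                SequenceRecord(
                    id=f"{label}_s{member}",
                    residues=residues,
                    label=label,
                )
            )
    order = rng.permutation(len(records))
    records = [records[i] for i in order]
    return SequenceSet(records=records, provenance="synthetic")


def generate_scalability_set(
    n_seqs: int,
    length: int,
    n_clusters: int = 10,
    seed: int = 0,
    substitution_rate: float = 0.05,
) -> SequenceSet:
    """Planted-cluster set for timing runs: ``n_clusters`` equal-size
    families of identical-length random sequences."""
    if n_seqs < n_clusters:
        raise ValueError("need at least one sequence per cluster")
    base = n_seqs // n_clusters
    sizes = [base + (1 if i < n_seqs % n_clusters else 0) for i in range(n_clusters)]
    model = FamilyModel(
        n_families=n_clusters,
        seqs_per_family=tuple(sizes),
        ancestor_lengths=tuple([length] * n_clusters),
        substitution_rate=substitution_rate,
        seed=seed,
    )
    return generate_families(model)
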