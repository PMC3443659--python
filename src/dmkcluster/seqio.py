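"""FASTA and label-file I/O with alphabet sanitization.

The feature model downstream assumes sequences over the pure nucleotide
alphabet {A, C, G, T}.  Everything read here is upper-cased and, by
default, stripped of any other character (ambiguity codes, gaps, N);
a strict ``reject`` policy is available for pipelines that must not
silently drop residues.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Mapping

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioRecord

logger = logging.getLogger(__name__)

ALPHABET = "ACGT"
_ACGT = frozenset(ALPHABET)


class SanitizeError(ValueError):
    """Raised when a sequence violates the ACGT alphabet under ``reject``."""


@dataclass(frozen=True)
class SequenceRecord:
    """One named DNA sequence with an optional class/family label."""

    id: str
    residues: str
    description: str = ""
    label: str | None = None

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("sequence id must be non-empty")
        if not self.residues:
            raise ValueError(f"sequence {self.id!r}: residues must be non-empty")
        bad = set(self.residues) - _ACGT
        if bad:
            raise ValueError(
                f"sequence {self.id!r}: non-ACGT characters {sorted(bad)} "
                "(sanitize first)"
            )

    def __len__(self) -> int:
        return len(self.residues)


@dataclass
class SequenceSet:
    """An ordered collection of records; the order is the canonical index
    order used by distance matrices and clustering outputs."""

    records: list[SequenceRecord] = field(default_factory=list)
    provenance: str = "unknown"

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for rec in self.records:
            if rec.id in seen:
                raise ValueError(f"duplicate sequence id {rec.id!r}")
            seen.add(rec.id)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[SequenceRecord]:
        return iter(self.records)

    def __getitem__(self, i: int) -> SequenceRecord:
        return self.records[i]

    @property
    def ids(self) -> list[str]:
        return [r.id for r in self.records]

    @property
    def labels(self) -> list[str | None]:
        return [r.label for r in self.records]

    def with_labels(self, label_map: Mapping[str, str]) -> "SequenceSet":
        """Return a copy with labels attached from ``id -> label`` mapping."""
        recs = [
            replace(r, label=label_map.get(r.id, r.label)) for r in self.records
        ]
        return SequenceSet(records=recs, provenance=self.provenance)


def sanitize(residues: str, policy: str = "strip") -> str:
    """Normalize a raw residue string to upper-case ACGT.

    policy="strip" removes every non-ACGT character (count is logged);
    policy="reject" raises :class:`SanitizeError` at the first offender,
    reporting its 1-based position.
    """
    if not residues:
        raise ValueError("empty residue string")
    upper = residues.upper()
    if policy == "reject":
        for pos, ch in enumerate(upper, start=1):
            if ch not in _ACGT:
                raise SanitizeError(
                    f"non-ACGT character {ch!r} at position {pos}"
                )
        return upper
    if policy != "strip":
        raise ValueError(f"unknown sanitize policy {policy!r}")
    clean = "".join(ch for ch in upper if ch in _ACGT)
    removed = len(upper) - len(clean)
    if removed:
        logger.info("sanitize: stripped %d non-ACGT character(s)", removed)
    return clean


def read_fasta(
    path: str | Path,
    label_map: Mapping[str, str] | None = None,
    policy: str = "strip",
) -> SequenceSet:
    """Read a multi-record FASTA file into a :class:`SequenceSet`.

    Records keep file order; residues are sanitized per ``policy``.
    Errors: no records, duplicate ids, or a record left empty after
    sanitization.
    """
    path = Path(path)
    records: list[SequenceRecord] = []
    for bio in SeqIO.parse(str(path), "fasta"):
        raw = str(bio.seq)
        if not raw:
            raise ValueError(f"record {bio.id!r}: empty sequence")
        clean = sanitize(raw, policy=policy)
        if not clean:
            raise ValueError(
                f"record {bio.id!r}: empty after removing non-ACGT characters"
            )
        label = label_map.get(bio.id) if label_map else None
        records.append(
            SequenceRecord(
                id=bio.id,
                residues=clean,
                description=bio.description,
                label=label,
            )
        )
    if not records:
        raise ValueError(f"no sequences in {path}")
    return SequenceSet(records=records, provenance=str(path))


def write_fasta(seqs: SequenceSet | Iterable[SequenceRecord], path: str | Path) -> None:
    """Write records to FASTA (60-column wrapped), preserving order."""
    recs = seqs.records if isinstance(seqs, SequenceSet) else list(seqs)
    bio_records = [
        _BioRecord(Seq(r.residues), id=r.id, description=r.description)
        for r in recs
    ]
    SeqIO.write(bio_records, str(path), "fasta")


def read_labels(path: str | Path) -> dict[str, str]:
    """Read a ``sequence_id<TAB>class_label`` TSV; '#' lines are comments."""
    labels: dict[str, str] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            raise ValueError(f"{path}:{lineno}: expected 'id<TAB>label'")
        seq_id, label = parts
        if seq_id in labels:
            raise ValueError(f"{path}:{lineno}: duplicate id {seq_id!r}")
        labels[seq_id] = label
    return labels


def write_labels(seqs: SequenceSet, path: str | Path) -> None:
    """Write the set's labels as a TSV sidecar (unlabelled records skipped)."""
    lines = [
        f"{r.id}\t{r.label}" for r in seqs.records if r.label is not None
    ]
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))
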