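"""Peptide FASTA input/output and record-level filtering.

Annotations are carried in FASTA headers as pipe-delimited tags after the
record id, e.g. ``>starPep_07237|Tumor Homing|Antimicrobial``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO

CANONICAL_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWY")
#: residues outside the canonical 20 that a permissive reader maps to X
NON_CANONICAL = frozenset("BJOUXZ")


class FastaError(ValueError):
    """Raised on malformed FASTA input or duplicate record ids."""


@dataclass(frozen=True)
class PeptideRecord:
    """A single peptide sequence with an id and free-form annotation tags."""

    id: str
    sequence: str
    annotations: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("peptide id must be non-empty")
        if not self.sequence:
            raise ValueError(f"{self.id}: sequence must be non-empty")
        object.__setattr__(self, "sequence", self.sequence.upper())
        object.__setattr__(self, "annotations", frozenset(self.annotations))

    @property
    def length(self) -> int:
        return len(self.sequence)

    def is_canonical(self) -> bool:
        return set(self.sequence) <= CANONICAL_ALPHABET


def _check_alphabet(rec: PeptideRecord, policy: str) -> PeptideRecord | None:
    bad = set(rec.sequence) - CANONICAL_ALPHABET
    if not bad:
        return rec
    if policy == "strict":
        raise FastaError(
            f"record {rec.id!r}: non-canonical residue(s) {sorted(bad)} "
            "(use policy='permissive' to map them to X)"
        )
    if policy == "permissive":
        if not bad <= NON_CANONICAL:
            raise FastaError(f"record {rec.id!r}: invalid residue(s) {sorted(bad)}")
        mapped = "".join("X" if c in NON_CANONICAL else c for c in rec.sequence)
        return PeptideRecord(rec.id, mapped, rec.annotations)
    raise ValueError(f"unknown alphabet policy {policy!r}")


def read_fasta(
    path: str | Path,
    annotation_parse: bool = True,
    policy: str = "strict",
) -> list[PeptideRecord]:
    """Read a multi-record FASTA file into :class:`PeptideRecord` objects.

    Parameters
    ----------
    path:
        FASTA file; wrapped or unwrapped sequence lines are accepted.
    annotation_parse:
        When true, pipe-delimited fields after the id in the header are
        attached as annotation tags.
    policy:
        ``"strict"`` rejects non-canonical residues; ``"permissive"`` maps
        B/J/O/U/X/Z to X.
    """
    path = Path(path)
    records: list[PeptideRecord] = []
    seen: dict[str, int] = {}
    try:
        parsed = list(SeqIO.parse(str(path), "fasta"))
    except ValueError as exc:  # Biopython names the offending content
        raise FastaError(f"{path}: malformed FASTA: {exc}") from exc
    for entry in parsed:
        header = entry.description or entry.id
        parts = header.split("|")
        rid = parts[0].strip()
        tags = (
            frozenset(p.strip() for p in parts[1:] if p.strip())
            if annotation_parse
            else frozenset()
        )
        seq = str(entry.seq).strip()
        if not seq:
            raise FastaError(f"{path}: record {rid!r} has an empty sequence")
        rec = _check_alphabet(PeptideRecord(rid, seq, tags), policy)
        seen[rid] = seen.get(rid, 0) + 1
        records.append(rec)
    dups = sorted(r for r, k in seen.items() if k > 1)
    if dups:
        raise FastaError(f"{path}: duplicate record ids: {dups}")
    return records


def write_fasta(records: Iterable[PeptideRecord], path: str | Path) -> Path:
    """Write records as unwrapped FASTA, annotations pipe-joined into headers."""
    path = Path(path)
    recs = list(records)
    ids = [r.id for r in recs]
    if len(set(ids)) != len(ids):
        raise FastaError("duplicate ids in output set")
    with open(path, "w") as fh:
        for rec in recs:
            header = rec.id
            if rec.annotations:
                header += "|" + "|".join(sorted(rec.annotations))
            fh.write(f">{header}\n{rec.sequence}\n")
    return path


def filter_records(
    records: Sequence[PeptideRecord],
    min_len: int = 1,
    max_len: int = 10**9,
    exclude_tags: Iterable[str] = (),
) -> list[PeptideRecord]:
    """Keep records with ``min_len <= length <= max_len`` (inclusive) whose
    annotations are disjoint from *exclude_tags*; input order is preserved."""
    if min_len < 1 or min_len > max_len:
        raise ValueError("require 1 <= min_len <= max_len")
    excl = frozenset(exclude_tags)
    return [
        r
        for r in records
        if min_len <= r.length <= max_len and not (r.annotations & excl)
    ]
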