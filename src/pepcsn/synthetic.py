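"""Seeded synthetic peptide datasets for exercising the full pipeline.

The generator emulates the family structure of a curated bioactive-peptide
set: each family is a cloud of point mutants around a seed sequence that
carries a short conserved motif, plus a background of unrelated random
peptides. Benchmark negatives are composition-preserving residue shuffles
of the positives, so descriptor-space separation is non-trivial.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .io import PeptideRecord

_AA = "ACDEFGHIKLMNPQRSTVWY"


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of the synthetic peptide-family generator.

    Defaults produce 100 peptides: 6 families of 12 mutants (lengths 10–22,
    8% per-position substitution outside the conserved motif) plus 28
    unrelated random peptides.
    """

    n_families: int = 6
    family_size: int = 12
    seed_motifs: tuple[str, ...] | None = None
    min_len: int = 10
    max_len: int = 22
    substitution_rate: float = 0.08
    n_unrelated: int = 28
    rng_seed: int = 2024

    def __post_init__(self) -> None:
        if not 0 <= self.substitution_rate < 1:
            raise ValueError("substitution_rate must lie in [0, 1)")
        if min(self.n_families, self.family_size, self.n_unrelated) < 0:
            raise ValueError("counts must be non-negative")
        if not 1 <= self.min_len <= self.max_len:
            raise ValueError("require 1 <= min_len <= max_len")


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(_AA), size=length))


def generate_families(
    spec: SyntheticSpec = SyntheticSpec(),
) -> tuple[list[PeptideRecord], dict[str, int]]:
    """Generate family-structured peptides plus unrelated background.

    Returns the records and a map from record id to family label
    (-1 marks unrelated peptides). Deterministic for a given ``rng_seed``.
    """
    rng = np.random.default_rng(spec.rng_seed)
    motifs = spec.seed_motifs
    if motifs is None:
        motifs = tuple(_random_seq(rng, 5) for _ in range(spec.n_families))
    if len(motifs) != spec.n_families:
        raise ValueError("need one seed motif per family")
    records: list[PeptideRecord] = []
    labels: dict[str, int] = {}
    for fam, motif in enumerate(motifs):
        length = int(rng.integers(max(spec.min_len, len(motif)), spec.max_len + 1))
        seed = list(_random_seq(rng, length))
        pos = int(rng.integers(0, length - len(motif) + 1))
        seed[pos : pos + len(motif)] = motif
        motif_sites = set(range(pos, pos + len(motif)))
        for m in range(spec.family_size):
            mutant = list(seed)
            for i in range(length):
                if i not in motif_sites and rng.random() < spec.substitution_rate:
                    mutant[i] = rng.choice(list(_AA.replace(mutant[i], "")))
            rid = f"fam{fam}_m{m}"
            records.append(PeptideRecord(rid, "".join(mutant)))
            labels[rid] = fam
    for u in range(spec.n_unrelated):
        length = int(rng.integers(spec.min_len, spec.max_len + 1))
        rid = f"unrel_{u}"
        records.append(PeptideRecord(rid, _random_seq(rng, length)))
        labels[rid] = -1
    return records, labels


def generate_benchmark(
    positives: Sequence[PeptideRecord], rng_seed: int = 2024
) -> tuple[list[PeptideRecord], list[PeptideRecord], dict[str, str]]:
    """Class-balanced benchmark: the positives plus one shuffled negative per
    positive (residue permutation, so amino-acid composition is preserved).

    Returns (positives, negatives, true labels by id).
    """
    if not positives:
        raise ValueError("need at least one positive record")
    rng = np.random.default_rng(rng_seed)
    negatives = []
    labels: dict[str, str] = {}
    for rec in positives:
        residues = list(rec.sequence)
        rng.shuffle(residues)
        neg = PeptideRecord(f"neg_{rec.id}", "".join(residues))
        negatives.append(neg)
        labels[rec.id] = "positive"
        labels[neg.id] = "negative"
    return list(positives), negatives, labels
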