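"""Physicochemical peptide descriptors and min–max normalization.

The ten default descriptors place each peptide in the coordinate-free
property space from which chemical space networks are built: length, net
charge at pH 7, isoelectric point, molecular weight, Boman index,
hydrophobic moment, average hydrophilicity, hydrophobic periodicity,
aliphatic index, and instability index.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio.SeqUtils.ProtParam import ProteinAnalysis

from . import scales
from .io import CANONICAL_ALPHABET, PeptideRecord

#: helical turn angle (degrees per residue) for moment and periodicity
HELIX_ANGLE_DEG = 100.0

DESCRIPTOR_NAMES = (
    "length",
    "net_charge",
    "isoelectric_point",
    "molecular_weight",
    "boman_index",
    "hydrophobic_moment",
    "avg_hydrophilicity",
    "hydrophobic_periodicity",
    "aliphatic_index",
    "instability_index",
)


def net_charge(sequence: str, ph: float = 7.0) -> float:
    """Henderson–Hasselbalch net charge at the given pH (Lehninger pKa set)."""

    def pos(pka: float) -> float:
        return 1.0 / (1.0 + 10 ** (ph - pka))

    def neg(pka: float) -> float:
        return 1.0 / (1.0 + 10 ** (pka - ph))

    charge = pos(scales.PKA_NTERM) - neg(scales.PKA_CTERM)
    for aa, pka in scales.PKA_POSITIVE.items():
        charge += sequence.count(aa) * pos(pka)
    for aa, pka in scales.PKA_NEGATIVE.items():
        charge -= sequence.count(aa) * neg(pka)
    return charge


def isoelectric_point(sequence: str, tol: float = 1e-4) -> float:
    """pH at which the net charge vanishes, by bisection on [0, 14]."""
    lo, hi = 0.0, 14.0
    if net_charge(sequence, lo) < 0:
        return lo
    if net_charge(sequence, hi) > 0:
        return hi
    while True:
        mid = (lo + hi) / 2
        c = net_charge(sequence, mid)
        if abs(c) < tol or hi - lo < 1e-9:
            return mid
        if c > 0:
            lo = mid
        else:
            hi = mid


def boman_index(sequence: str) -> float:
    return float(np.mean([scales.BOMAN[a] for a in sequence]))


def avg_hydrophilicity(sequence: str) -> float:
    return float(np.mean([scales.HOPP_WOODS[a] for a in sequence]))


def hydrophobic_moment(sequence: str, angle_deg: float = HELIX_ANGLE_DEG) -> float:
    """Eisenberg helical hydrophobic moment per residue (dimensionless)."""
    delta = math.radians(angle_deg)
    h = [scales.EISENBERG[a] for a in sequence]
    s = sum(hi * math.sin(delta * i) for i, hi in enumerate(h))
    c = sum(hi * math.cos(delta * i) for i, hi in enumerate(h))
    return math.hypot(s, c) / len(h)


def hydrophobic_periodicity(sequence: str, angle_deg: float = HELIX_ANGLE_DEG) -> float:
    """Normalized amplitude of the mean-centred hydrophobicity profile's
    Fourier component at the helical frequency; in [0, 1], with 1 meaning a
    perfectly periodic amphipathic pattern."""
    h = np.array([scales.EISENBERG[a] for a in sequence], dtype=float)
    centred = h - h.mean()
    norm = np.abs(centred).sum()
    if norm == 0:
        return 0.0
    omega = math.radians(angle_deg)
    phases = np.exp(1j * omega * np.arange(len(h)))
    return float(abs((centred * phases).sum()) / norm)


def aliphatic_index(sequence: str) -> float:
    """Ikai aliphatic index from mole fractions of A, V, I and L."""
    n = len(sequence)
    xa = sequence.count("A") / n
    xv = sequence.count("V") / n
    xil = (sequence.count("I") + sequence.count("L")) / n
    return 100.0 * (xa + 2.9 * xv + 3.9 * xil)


@dataclass(frozen=True)
class DescriptorVector:
    peptide_id: str
    values: dict[str, float]

    def __post_init__(self) -> None:
        bad = {k: v for k, v in self.values.items() if not math.isfinite(v)}
        if bad:
            raise ValueError(f"{self.peptide_id}: non-finite descriptor(s) {bad}")


@dataclass
class DescriptorMatrix:
    """Peptides × descriptors table; ``normalized`` marks min–max scaling."""

    data: pd.DataFrame
    normalized: bool = False

    @property
    def peptide_ids(self) -> list[str]:
        return list(self.data.index)


def compute_descriptors(
    record: PeptideRecord, descriptor_set: Sequence[str] = DESCRIPTOR_NAMES
) -> DescriptorVector:
    seq = record.sequence
    if set(seq) - CANONICAL_ALPHABET:
        raise ValueError(
            f"{record.id}: descriptors require canonical residues only"
        )
    pa = ProteinAnalysis(seq)
    full = {
        "length": float(len(seq)),
        "net_charge": net_charge(seq),
        "isoelectric_point": isoelectric_point(seq),
        "molecular_weight": pa.molecular_weight(),
        "boman_index": boman_index(seq),
        "hydrophobic_moment": hydrophobic_moment(seq),
        "avg_hydrophilicity": avg_hydrophilicity(seq),
        "hydrophobic_periodicity": hydrophobic_periodicity(seq),
        "aliphatic_index": aliphatic_index(seq),
        "instability_index": pa.instability_index() if len(seq) > 1 else 0.0,
    }
    unknown = set(descriptor_set) - set(full)
    if unknown:
        raise ValueError(f"unknown descriptor(s): {sorted(unknown)}")
    return DescriptorVector(record.id, {k: full[k] for k in descriptor_set})


def descriptor_matrix(
    records: Iterable[PeptideRecord],
    descriptor_set: Sequence[str] = DESCRIPTOR_NAMES,
) -> DescriptorMatrix:
    vectors = [compute_descriptors(r, descriptor_set) for r in records]
    if not vectors:
        raise ValueError("no records")
    df = pd.DataFrame(
        [v.values for v in vectors], index=[v.peptide_id for v in vectors]
    )
    return DescriptorMatrix(df, normalized=False)


def minmax_normalize(matrix: DescriptorMatrix) -> DescriptorMatrix:
    """Map every column to [0, 1] by (x − min)/(max − min).

    Constant columns carry no distance information and are mapped to 0.
    """
    if len(matrix.data) < 2:
        raise ValueError("normalization requires at least 2 peptides")
    df = matrix.data.astype(float)
    mins, maxs = df.min(axis=0), df.max(axis=0)
    span = maxs - mins
    out = pd.DataFrame(0.0, index=df.index, columns=df.columns)
    varying = span > 0
    out.loc[:, varying] = (df.loc[:, varying] - mins[varying]) / span[varying]
    return DescriptorMatrix(out, normalized=True)
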