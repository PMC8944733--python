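"""Smith–Waterman local-alignment identity scoring.

The identity score between two peptides is the number of identical columns
in the optimal local alignment under BLOSUM62 with affine gap penalties,
normalized to [0, 1]. The default normalization divides by the length of
the shorter sequence, so an exact substring hit scores 1.0 while a short
chance match between unrelated peptides scores low — the behavior required
for identity thresholds (e.g. 0.6) to discriminate random sequences. An
alternative mode divides by the aligned columns of the optimal alignment
(gapped columns included). A pair with no positive-scoring local alignment
(empty optimum) scores 0.
"""

from __future__ import annotations

import functools
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices

from .io import PeptideRecord


@dataclass(frozen=True)
class AlignmentParams:
    """Scoring scheme for pairwise alignment.

    Gap penalties are stored as the (non-negative) costs of opening and
    extending a gap. ``gap_open`` is the cost of the first residue of a gap.
    """

    substitution_matrix: str = "BLOSUM62"
    gap_open: float = 10.0
    gap_extend: float = 1.0
    mode: str = "local"
    normalization: str = "shorter"  # "shorter" | "aligned_columns"

    def __post_init__(self) -> None:
        if self.gap_open < 0 or self.gap_extend < 0:
            raise ValueError("gap penalties must be non-negative")
        if self.gap_extend > self.gap_open:
            raise ValueError("gap_extend must not exceed gap_open")
        if self.mode not in ("local", "global"):
            raise ValueError(f"unknown alignment mode {self.mode!r}")
        if self.normalization not in ("shorter", "aligned_columns"):
            raise ValueError(f"unknown normalization {self.normalization!r}")


@dataclass(frozen=True)
class IdentityScore:
    """Identity of an optimal local alignment.

    ``value`` is ``n_identities`` over the normalization denominator chosen
    in :class:`AlignmentParams` (shorter-sequence length by default, aligned
    columns otherwise), clipped to [0, 1]; 0 when the optimum is empty.
    """

    value: float
    n_identities: int
    alignment_length: int


DEFAULT_PARAMS = AlignmentParams()


@functools.lru_cache(maxsize=8)
def _aligner(params: AlignmentParams) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = params.mode
    aligner.substitution_matrix = substitution_matrices.load(
        params.substitution_matrix
    )
    aligner.open_gap_score = -params.gap_open
    aligner.extend_gap_score = -params.gap_extend
    return aligner


def _seq(x: PeptideRecord | str) -> str:
    return x.sequence if isinstance(x, PeptideRecord) else x


@functools.lru_cache(maxsize=200_000)
def _identity_cached(sa: str, sb: str, params: AlignmentParams) -> IdentityScore:
    aligner = _aligner(params)
    if params.mode == "local" and aligner.score(sa, sb) <= 0:
        return IdentityScore(0.0, 0, 0)
    aln = aligner.align(sa, sb)[0]
    counts = aln.counts()
    length = counts.identities + counts.mismatches + counts.gaps
    if length == 0:
        return IdentityScore(0.0, 0, 0)
    denom = min(len(sa), len(sb)) if params.normalization == "shorter" else length
    return IdentityScore(
        min(counts.identities / denom, 1.0), counts.identities, length
    )


def identity(
    a: PeptideRecord | str,
    b: PeptideRecord | str,
    params: AlignmentParams = DEFAULT_PARAMS,
) -> IdentityScore:
    """Identity score of the optimal alignment of *a* and *b*.

    Symmetric by construction: the pair is canonically ordered before the
    alignment, so ``identity(a, b) == identity(b, a)`` exactly.
    """
    sa, sb = _seq(a), _seq(b)
    if not sa or not sb:
        raise ValueError("cannot align an empty sequence")
    if sb < sa:
        sa, sb = sb, sa
    return _identity_cached(sa, sb, params)


def pairwise_identity_matrix(
    records: Sequence[PeptideRecord],
    params: AlignmentParams = DEFAULT_PARAMS,
) -> np.ndarray:
    """Symmetric matrix of pairwise identity scores; unit diagonal."""
    if len(records) < 1:
        raise ValueError("need at least one record")
    n = len(records)
    mat = np.ones((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            mat[i, j] = mat[j, i] = identity(records[i], records[j], params).value
    return mat


def redundancy_filter(
    records: Sequence[PeptideRecord],
    cutoff: float = 0.98,
    params: AlignmentParams = DEFAULT_PARAMS,
    priority: Sequence[float] | None = None,
) -> list[PeptideRecord]:
    """Greedy removal of sequences more than *cutoff* identical to a kept one.

    Records are swept in input order (or descending *priority* score when
    given, ties by input order); a record is kept iff its identity to every
    already-kept record is <= cutoff. Matches the "higher than 98%/95%
    similarity removed" convention: the boundary value itself is retained,
    except that full-identity duplicates (identity 1.0) are always removed,
    so a cutoff of 1.0 removes exactly the duplicates.
    """
    if not 0 < cutoff <= 1:
        raise ValueError("cutoff must be in (0, 1]")
    order = list(range(len(records)))
    if priority is not None:
        if len(priority) != len(records):
            raise ValueError("priority list length mismatch")
        order.sort(key=lambda i: (-priority[i], i))
    kept: list[PeptideRecord] = []
    for i in order:
        rec = records[i]
        vals = (identity(rec, k, params).value for k in kept)
        if all(v <= cutoff and v < 1.0 for v in vals):
            kept.append(rec)
    if priority is None:
        return kept
    pos = {r.id: i for i, r in enumerate(records)}
    return sorted(kept, key=lambda r: pos[r.id])
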