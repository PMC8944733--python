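"""Centrality-ranked scaffold extraction and query-model assembly.

Scaffold extraction walks the peptides in descending centrality order and
keeps a peptide only when its alignment identity to every peptide already
kept is strictly below the cutoff, yielding a representative non-redundant
subset. Query models bundle such subsets (optionally with CSN singletons)
with an identity threshold θ into a similarity-searching classifier.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

from .alignment import DEFAULT_PARAMS, AlignmentParams, identity
from .centrality import CentralityTable
from .io import PeptideRecord


@dataclass
class QueryModel:
    """A multi-query similarity-searching model (SSM): the query peptides
    plus the identity threshold θ at which a target is called positive."""

    name: str
    queries: list[PeptideRecord]
    theta: float
    params: AlignmentParams = DEFAULT_PARAMS
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.queries:
            raise ValueError("query model needs at least one query")
        ids = [q.id for q in self.queries]
        if len(set(ids)) != len(ids):
            raise ValueError("query ids must be unique")
        if not 0 <= self.theta <= 1:
            raise ValueError("theta must lie in [0, 1]")


def scaffold_extract(
    records: Sequence[PeptideRecord],
    centrality: CentralityTable,
    identity_cutoff: float,
    params: AlignmentParams = DEFAULT_PARAMS,
) -> list[PeptideRecord]:
    """Greedy centrality-ranked redundancy removal at an identity cutoff.

    The most central record is always kept; every dropped record has
    identity >= cutoff to some kept record of higher rank, and the output's
    pairwise identities are all strictly below the cutoff.
    """
    if not 0 < identity_cutoff <= 1:
        raise ValueError("identity_cutoff must be in (0, 1]")
    scores = centrality.normalized()
    missing = [r.id for r in records if r.id not in scores.index]
    if missing:
        raise ValueError(f"records without centrality scores: {missing}")
    ranked = sorted(records, key=lambda r: (-scores[r.id], r.id))
    kept: list[PeptideRecord] = []
    for rec in ranked:
        if all(identity(rec, k, params).value < identity_cutoff for k in kept):
            kept.append(rec)
    return kept


def prune_by_top_centrality(
    records: Sequence[PeptideRecord],
    centrality: CentralityTable,
    drop_fraction: float = 0.10,
) -> list[PeptideRecord]:
    """Keep records whose normalized centrality is within *drop_fraction* of
    the most central record of the input set (the "30 + 10%" variant)."""
    if not 0 <= drop_fraction < 1:
        raise ValueError("drop_fraction must lie in [0, 1)")
    scores = centrality.normalized()
    top = max(scores[r.id] for r in records)
    cut = (1.0 - drop_fraction) * top
    return [r for r in records if scores[r.id] >= cut]


def build_query_model(
    name: str,
    sets: Sequence[Sequence[PeptideRecord]],
    theta: float,
    params: AlignmentParams = DEFAULT_PARAMS,
    provenance: dict | None = None,
) -> QueryModel:
    """Union the given record sets by id (first occurrence wins) into an SSM."""
    seen: dict[str, PeptideRecord] = {}
    for s in sets:
        for rec in s:
            seen.setdefault(rec.id, rec)
    prov = dict(provenance or {})
    prov.setdefault("set_sizes", [len(s) for s in sets])
    prov["n_queries"] = len(seen)
    return QueryModel(name, list(seen.values()), theta, params, prov)
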