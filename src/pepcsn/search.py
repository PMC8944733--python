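"""Group-fusion (MAX-SIM) multi-query similarity searching.

Each target peptide S is scored against every query Q of a model by
Smith–Waterman identity; the fused score of S is the maximum identity over
the queries. Targets with fused score >= θ are called positive. The module
also provides the hierarchical prospective-screening pipeline and the
3-nearest-neighbor "visual mining" report against a reference peptide set.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import pandas as pd

from .alignment import identity, redundancy_filter
from .descriptors import DescriptorMatrix, descriptor_matrix, minmax_normalize
from .io import PeptideRecord, filter_records
from .network import similarity_matrix
from .scaffold import QueryModel

#: decimals used when testing a fused score for exact-match (score-1) removal
_SCORE_DECIMALS = 6


@dataclass
class SearchHit:
    target_id: str
    fused_score: float
    best_query_id: str
    predicted_label: str | None = None  # "positive" | "negative" once θ applied


def fused_scores(model: QueryModel, targets: Sequence[PeptideRecord]) -> list[SearchHit]:
    """MAX-SIM fused score of every target against the model's queries.

    The best query is the arg-max; ties resolve to the lowest query id.
    """
    if not targets:
        raise ValueError("no target records")
    hits = []
    for s in targets:
        best_score, best_q = -1.0, None
        for q in sorted(model.queries, key=lambda r: r.id):
            val = identity(s, q, model.params).value
            if val > best_score:
                best_score, best_q = val, q.id
        hits.append(SearchHit(s.id, best_score, best_q))
    return hits


def classify(hits: Sequence[SearchHit], theta: float) -> list[SearchHit]:
    """Label hits positive iff fused score >= θ (inclusive boundary)."""
    if not 0 <= theta <= 1:
        raise ValueError("theta must lie in [0, 1]")
    return [
        SearchHit(
            h.target_id,
            h.fused_score,
            h.best_query_id,
            "positive" if h.fused_score >= theta else "negative",
        )
        for h in hits
    ]


def hits_table(hits: Sequence[SearchHit]) -> pd.DataFrame:
    df = pd.DataFrame(
        [
            {
                "target_id": h.target_id,
                "fused_score": h.fused_score,
                "best_query": h.best_query_id,
                "label": h.predicted_label,
            }
            for h in hits
        ]
    )
    return df.sort_values(
        ["fused_score", "target_id"], ascending=[False, True]
    ).reset_index(drop=True)


@dataclass
class ScreeningConfig:
    """Stage parameters of the hierarchical prospective screen."""

    min_len: int = 3
    max_len: int = 25
    exclude_tags: frozenset[str] = field(
        default_factory=lambda: frozenset({"Tumor Homing", "Toxic"})
    )
    redundancy_cutoff: float = 0.95
    theta: float = 0.60
    drop_perfect: bool = True  # remove fused score == 1 (known peptides)


def prospective_screen(
    db: Sequence[PeptideRecord],
    model: QueryModel,
    config: ScreeningConfig = ScreeningConfig(),
) -> tuple[list[SearchHit], dict[str, int]]:
    """Run the hierarchical screen: metadata/length filter → redundancy
    filter → MAX-SIM search at θ → optional removal of perfect matches.

    Returns the ranked positive hits and a per-stage record-count log.
    """
    log: dict[str, int] = {"input": len(db)}
    stage1 = filter_records(db, config.min_len, config.max_len, config.exclude_tags)
    log["after_length_tag_filter"] = len(stage1)
    if not stage1:
        return [], log
    stage2 = redundancy_filter(stage1, config.redundancy_cutoff, model.params)
    log["after_redundancy_filter"] = len(stage2)
    if not stage2:
        return [], log
    labeled = classify(fused_scores(model, stage2), config.theta)
    positives = [h for h in labeled if h.predicted_label == "positive"]
    log["predicted_positive"] = len(positives)
    if config.drop_perfect:
        positives = [
            h for h in positives if round(h.fused_score, _SCORE_DECIMALS) != 1.0
        ]
    log["after_perfect_match_removal"] = len(positives)
    positives.sort(key=lambda h: (-h.fused_score, h.target_id))
    return positives, log


def nearest_known_neighbors(
    hits: Sequence[PeptideRecord],
    reference: Sequence[PeptideRecord],
    threshold: float,
    k: int = 3,
    descriptor_set: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Embed hits into the reference CSN and report each hit's k most
    similar directly-attached reference peptides.

    Similarity is descriptor-space CSN similarity computed jointly over
    reference ∪ hits; only reference nodes at or above the CSN threshold
    qualify as neighbors. Hits sharing >= 2 of their k neighbors are flagged
    as redundant candidates.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    hit_ids = {h.id for h in hits}
    ref_ids = [r.id for r in reference if r.id not in hit_ids]
    pool = list(reference) + [h for h in hits if h.id not in {r.id for r in reference}]
    kwargs = {"descriptor_set": descriptor_set} if descriptor_set else {}
    sim = similarity_matrix(minmax_normalize(descriptor_matrix(pool, **kwargs)))
    rows = []
    neighbor_sets: dict[str, frozenset[str]] = {}
    for h in hits:
        sims = sim.loc[h.id, ref_ids]
        attached = sims[sims >= threshold].sort_values(ascending=False)
        top = attached.iloc[:k]
        neighbor_sets[h.id] = frozenset(top.index)
        for rank, (ref_id, s) in enumerate(top.items(), start=1):
            rows.append(
                {"hit_id": h.id, "rank": rank, "neighbor_id": ref_id,
                 "similarity": float(s)}
            )
    df = pd.DataFrame(rows, columns=["hit_id", "rank", "neighbor_id", "similarity"])
    flagged = {
        a
        for a in neighbor_sets
        for b in neighbor_sets
        if a != b and len(neighbor_sets[a] & neighbor_sets[b]) >= 2
    }
    df["redundant_candidate"] = df["hit_id"].map(lambda x: x in flagged) if len(df) else []
    return df
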