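"""End-to-end orchestration: model building and retrospective evaluation.

``build_model_pipeline`` runs the full model-construction sequence on a
positive peptide set: 98% identity dedup → descriptor CSN at the working
threshold → outlier split → Louvain communities → per-centrality scaffold
extraction → union with the outlier set into a query model.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

from .alignment import DEFAULT_PARAMS, AlignmentParams, redundancy_filter
from .centrality import compute_centrality
from .descriptors import DESCRIPTOR_NAMES, descriptor_matrix, minmax_normalize
from .evaluation import MetricsReport, confusion, metrics
from .io import PeptideRecord, write_fasta
from .network import build_csn, detect_communities, export_graphml, split_giant_outliers
from .scaffold import QueryModel, build_query_model, scaffold_extract
from .search import classify, fused_scores


@dataclass
class PipelineConfig:
    params: AlignmentParams = DEFAULT_PARAMS
    descriptor_set: tuple[str, ...] = DESCRIPTOR_NAMES
    dedup_cutoff: float = 0.98
    csn_threshold: float = 0.60
    centrality_measures: tuple[str, ...] = ("harmonic", "weighted_degree")
    scaffold_cutoff: float = 0.60
    theta: float = 0.60
    include_outliers: bool = True
    rng_seed: int = 42

    def __post_init__(self) -> None:
        for t in (self.dedup_cutoff, self.csn_threshold, self.scaffold_cutoff, self.theta):
            if not 0 <= t <= 1:
                raise ValueError("all thresholds must lie in [0, 1]")

    def as_dict(self) -> dict:
        d = asdict(self)
        d["params"] = asdict(self.params)
        return d


def build_model_pipeline(
    records: Sequence[PeptideRecord],
    config: PipelineConfig = PipelineConfig(),
    name: str = "model",
    out_dir: str | Path | None = None,
) -> tuple[QueryModel, dict]:
    """Build a query model from a positive peptide set.

    Returns the model and a stage log with record counts. When *out_dir* is
    given, the query FASTA, the CSN GraphML, and the config/stage log are
    written there.
    """
    log: dict = {"config": config.as_dict(), "stages": {"input": len(records)}}
    stages = log["stages"]

    deduped = redundancy_filter(records, config.dedup_cutoff, config.params)
    stages["after_dedup"] = len(deduped)
    if len(deduped) < 2:
        raise ValueError("pipeline needs at least 2 non-redundant records")

    dm = minmax_normalize(descriptor_matrix(deduped, config.descriptor_set))
    net = build_csn(dm, config.csn_threshold, provenance=config.as_dict())
    stages["csn_nodes"] = net.n_nodes
    stages["csn_edges"] = net.n_edges

    giant, outlier_ids = split_giant_outliers(net)
    stages["outliers"] = len(outlier_ids)
    stages["giant_nodes"] = giant.n_nodes
    by_id = {r.id: r for r in deduped}
    outlier_records = [by_id[i] for i in outlier_ids]
    giant_records = [by_id[i] for i in giant.nodes]

    sets: list[list[PeptideRecord]] = []
    set_names: list[str] = []
    if giant.n_nodes > 0 and giant.n_edges > 0:
        detect_communities(giant, config.rng_seed)
        for measure in config.centrality_measures:
            table = compute_centrality(giant, measure)
            extracted = scaffold_extract(
                giant_records, table, config.scaffold_cutoff, config.params
            )
            stages[f"scaffold_{measure}"] = len(extracted)
            sets.append(extracted)
            set_names.append(measure)
    if config.include_outliers and outlier_records:
        sets.append(outlier_records)
        set_names.append("outliers")
    if not sets:
        raise ValueError("no query sets produced; lower the CSN threshold")

    model = build_query_model(
        name,
        sets,
        config.theta,
        config.params,
        provenance={"sets": set_names, "config": config.as_dict()},
    )
    stages["n_queries"] = len(model.queries)

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_fasta(model.queries, out / f"{name}_queries.fasta")
        export_graphml(net, out / f"{name}_csn.graphml")
        (out / f"{name}_log.json").write_text(json.dumps(log, indent=2))
    return model, log


def evaluate_pipeline(
    model: QueryModel,
    positives: Sequence[PeptideRecord],
    negatives: Sequence[PeptideRecord],
    theta: float | None = None,
) -> MetricsReport:
    """Retrospective similarity searching against a labeled benchmark."""
    theta = model.theta if theta is None else theta
    targets = list(positives) + list(negatives)
    labeled = classify(fused_scores(model, targets), theta)
    predicted = [h.predicted_label for h in labeled]
    true = ["positive"] * len(positives) + ["negative"] * len(negatives)
    return metrics(confusion(predicted, true))
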