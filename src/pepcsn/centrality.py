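"""Node-centrality measures used to rank peptides within a CSN.

Four measures are supported: weighted degree (sum of incident edge
similarities), harmonic centrality and betweenness (both on unweighted
hops), and community hub-bridge, a modular-network measure combining
community-size-weighted intra-community degree with
neighbor-community-weighted inter-community degree:

    CHB(u) = |C(u)| · k_intra(u) + NNC(u) · k_inter(u)

where C(u) is u's community, k_intra/k_inter its intra-/inter-community
degree and NNC(u) the number of distinct neighboring communities.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import pandas as pd

from .network import SimilarityNetwork

MEASURES = ("weighted_degree", "harmonic", "betweenness", "community_hub_bridge")


@dataclass
class CentralityTable:
    measure: str
    scores: pd.DataFrame  # columns: raw, normalized; index: node id

    def normalized(self) -> pd.Series:
        return self.scores["normalized"]


def _community_hub_bridge(g: nx.Graph, labels: dict[str, int]) -> dict[str, float]:
    sizes: dict[int, int] = {}
    for c in labels.values():
        sizes[c] = sizes.get(c, 0) + 1
    out = {}
    for u in g.nodes:
        cu = labels[u]
        k_intra = k_inter = 0
        neigh_comms = set()
        for v in g.neighbors(u):
            if labels[v] == cu:
                k_intra += 1
            else:
                k_inter += 1
                neigh_comms.add(labels[v])
        out[u] = sizes[cu] * k_intra + len(neigh_comms) * k_inter
    return out


def compute_centrality(
    net: SimilarityNetwork,
    measure: str,
    communities: dict[str, int] | None = None,
) -> CentralityTable:
    """Raw and min–max-normalized scores for one centrality measure."""
    g = net.graph
    if g.number_of_nodes() == 0:
        raise ValueError("empty network")
    if measure == "weighted_degree":
        raw = dict(g.degree(weight="weight"))
    elif measure == "harmonic":
        raw = nx.harmonic_centrality(g)
    elif measure == "betweenness":
        raw = nx.betweenness_centrality(g, normalized=False, weight=None)
    elif measure == "community_hub_bridge":
        labels = communities if communities is not None else net.communities
        if labels is None:
            raise ValueError("community_hub_bridge requires community labels")
        raw = _community_hub_bridge(g, labels)
    else:
        raise ValueError(f"unknown centrality measure {measure!r}")
    s = pd.Series(raw, dtype=float)
    lo, hi = s.min(), s.max()
    norm = pd.Series(0.0, index=s.index) if hi == lo else (s - lo) / (hi - lo)
    return CentralityTable(measure, pd.DataFrame({"raw": s, "normalized": norm}))


def rank_nodes(table: CentralityTable) -> list[str]:
    """Node ids in descending normalized score; ties broken lexicographically."""
    s = table.scores["normalized"]
    return sorted(s.index, key=lambda n: (-s[n], n))
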