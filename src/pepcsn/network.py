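"""Chemical space networks (CSNs) over peptide descriptor space.

Nodes are peptides; two peptides are joined when their similarity — one
minus the min–max-normalized Euclidean distance between their normalized
descriptor vectors — reaches the working threshold. The normalization is
dataset-relative: distances are rescaled over all unordered pairs of the
current input set, so similarity is context-dependent by design.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy.spatial.distance import squareform, pdist

from .descriptors import DescriptorMatrix

DEFAULT_LOUVAIN_SEED = 42


@dataclass
class SimilarityNetwork:
    """A weighted undirected CSN at a stated similarity threshold."""

    graph: nx.Graph
    threshold: float
    communities: dict[str, int] | None = None
    provenance: dict = field(default_factory=dict)

    @property
    def nodes(self) -> list[str]:
        return list(self.graph.nodes)

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()


@dataclass
class NetworkMetrics:
    n_nodes: int
    n_edges: int
    density: float
    average_degree: float
    average_clustering_coefficient: float
    diameter: int
    average_path_length: float
    n_triangles: int
    n_singletons: int
    n_communities: int | None = None
    modularity: float | None = None

    def as_dict(self) -> dict:
        return dict(self.__dict__)


def similarity_matrix(matrix: DescriptorMatrix) -> pd.DataFrame:
    """Pairwise descriptor-space similarity: 1 − min–max-scaled Euclidean
    distance over all unordered pairs of the input set."""
    if not matrix.normalized:
        raise ValueError("descriptor matrix must be min–max normalized")
    if len(matrix.data) < 2:
        raise ValueError("need at least 2 peptides")
    d = pdist(matrix.data.to_numpy(float), metric="euclidean")
    dmin, dmax = d.min(), d.max()
    scaled = np.zeros_like(d) if dmax == dmin else (d - dmin) / (dmax - dmin)
    sim = 1.0 - squareform(scaled)
    np.fill_diagonal(sim, 1.0)
    ids = matrix.peptide_ids
    return pd.DataFrame(sim, index=ids, columns=ids)


def _graph_from_similarity(sim: pd.DataFrame, t: float) -> nx.Graph:
    g = nx.Graph()
    ids = list(sim.index)
    g.add_nodes_from(ids)
    arr = sim.to_numpy()
    n = len(ids)
    for i in range(n):
        for j in range(i + 1, n):
            if arr[i, j] >= t:
                g.add_edge(ids[i], ids[j], weight=float(arr[i, j]))
    return g


def build_csn(
    matrix: DescriptorMatrix, t: float, provenance: dict | None = None
) -> SimilarityNetwork:
    """Build the CSN at similarity threshold *t* in [0, 1].

    All peptides appear as nodes; isolated nodes are permitted.
    """
    if not 0 <= t <= 1:
        raise ValueError("threshold must lie in [0, 1]")
    sim = similarity_matrix(matrix)
    g = _graph_from_similarity(sim, t)
    return SimilarityNetwork(g, t, provenance=dict(provenance or {}))


def detect_communities(
    net: SimilarityNetwork, rng_seed: int = DEFAULT_LOUVAIN_SEED
) -> tuple[dict[str, int], float]:
    """Louvain partition on edge weights; returns labels and its (weighted)
    Newman modularity. An edgeless network trivially yields one community
    per node with modularity 0."""
    g = net.graph
    if g.number_of_nodes() == 0:
        raise ValueError("empty network")
    if g.number_of_edges() == 0:
        labels = {n: i for i, n in enumerate(g.nodes)}
        net.communities = labels
        return labels, 0.0
    parts = nx.community.louvain_communities(g, weight="weight", seed=rng_seed)
    labels = {n: i for i, part in enumerate(parts) for n in part}
    q = nx.community.modularity(g, parts, weight="weight")
    net.communities = labels
    for n, c in labels.items():
        g.nodes[n]["community"] = c
    return labels, float(q)


def split_giant_outliers(
    net: SimilarityNetwork,
) -> tuple[SimilarityNetwork, list[str]]:
    """Separate degree-0 nodes (outliers/singletons) from the connected part."""
    g = net.graph
    outliers = [n for n in g.nodes if g.degree(n) == 0]
    sub = g.subgraph(n for n in g.nodes if g.degree(n) > 0).copy()
    comms = (
        {n: c for n, c in (net.communities or {}).items() if n in sub}
        or None
    )
    return (
        SimilarityNetwork(sub, net.threshold, comms, dict(net.provenance)),
        outliers,
    )


def network_metrics(
    net: SimilarityNetwork, communities: dict[str, int] | None = None
) -> NetworkMetrics:
    """Global topology summary of a CSN.

    Diameter and average path length are computed on the largest connected
    component in unweighted hops; density and average degree on the full
    node set of *net*.
    """
    g = net.graph
    n, e = g.number_of_nodes(), g.number_of_edges()
    if n == 0:
        raise ValueError("empty network")
    density = 0.0 if n < 2 else 2 * e / (n * (n - 1))
    acc = nx.average_clustering(g) if n > 0 else 0.0
    if e > 0:
        giant = max(nx.connected_components(g), key=len)
        gg = g.subgraph(giant)
        diameter = nx.diameter(gg)
        apl = nx.average_shortest_path_length(gg)
    else:
        diameter, apl = 0, 0.0
    comms = communities if communities is not None else net.communities
    n_comm = mod = None
    if comms:
        groups: dict[int, set] = {}
        for node, c in comms.items():
            groups.setdefault(c, set()).add(node)
        n_comm = len(groups)
        mod = float(
            nx.community.modularity(g, list(groups.values()), weight="weight")
        )
    return NetworkMetrics(
        n_nodes=n,
        n_edges=e,
        density=density,
        average_degree=2 * e / n,
        average_clustering_coefficient=acc,
        diameter=diameter,
        average_path_length=apl,
        n_triangles=int(sum(nx.triangles(g).values()) / 3),
        n_singletons=sum(1 for v in g.nodes if g.degree(v) == 0),
        n_communities=n_comm,
        modularity=mod,
    )


def threshold_scan(
    matrix: DescriptorMatrix,
    t_values: Sequence[float],
    rng_seed: int = DEFAULT_LOUVAIN_SEED,
) -> pd.DataFrame:
    """Metrics table for CSNs built at each threshold in *t_values*.

    The similarity matrix is computed once; edge count and density are
    anti-monotone in the threshold.
    """
    if len(t_values) == 0:
        raise ValueError("t_values must be non-empty")
    sim = similarity_matrix(matrix)
    rows = []
    for t in t_values:
        net = SimilarityNetwork(_graph_from_similarity(sim, t), t)
        if net.n_edges > 0:
            detect_communities(net, rng_seed)
        m = network_metrics(net)
        rows.append({"threshold": t, **m.as_dict()})
    return pd.DataFrame(rows)


def export_graphml(net: SimilarityNetwork, path: str | Path) -> Path:
    """Write the CSN as GraphML with edge weights, community labels when
    present, and the threshold as a graph attribute."""
    g = net.graph.copy()
    g.graph["similarity_threshold"] = net.threshold
    if net.communities:
        for node, c in net.communities.items():
            if node in g:
                g.nodes[node]["community"] = int(c)
    nx.write_graphml(g, str(path))
    return Path(path)


def read_graphml(path: str | Path) -> SimilarityNetwork:
    g = nx.read_graphml(str(path))
    t = float(g.graph.get("similarity_threshold", 0.0))
    comms = {
        n: int(d["community"]) for n, d in g.nodes(data=True) if "community" in d
    } or None
    return SimilarityNetwork(g, t, comms)
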