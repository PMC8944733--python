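"""Independent brute-force oracles used only by the test suite.

These deliberately re-derive quantities from first principles (plain DP
recurrences, exhaustive path enumeration, closed-form formulas) so that the
implementation under test is checked against a second, independent route.
"""

from __future__ import annotations

import itertools
import math

from Bio.Align import substitution_matrices

_B62 = substitution_matrices.load("BLOSUM62")

NEG_INF = float("-inf")


def sw_gotoh(a: str, b: str, gap_open: float = 10.0, gap_extend: float = 1.0):
    """Brute-force Smith–Waterman with affine gaps (Gotoh three-matrix DP).

    Returns (best_score, best_identity_fractions) where the fractions are
    the set of identities/aligned-columns achievable by optimal-score local
    alignments, together with the set of identities/min-length values.
    Written independently of the package's alignment module.
    """
    n, m = len(a), len(b)
    # M: ends in match/mismatch; X: gap in b (consumes a); Y: gap in a
    M = [[0.0] * (m + 1) for _ in range(n + 1)]
    X = [[NEG_INF] * (m + 1) for _ in range(n + 1)]
    Y = [[NEG_INF] * (m + 1) for _ in range(n + 1)]
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = _B62[a[i - 1]][b[j - 1]]
            M[i][j] = max(0.0, M[i - 1][j - 1], X[i - 1][j - 1], Y[i - 1][j - 1]) + s
            X[i][j] = max(M[i - 1][j] - gap_open, X[i - 1][j] - gap_extend)
            Y[i][j] = max(M[i][j - 1] - gap_open, Y[i][j - 1] - gap_extend)
            best = max(best, M[i][j], X[i][j], Y[i][j])
    if best <= 0:
        return 0.0, {0.0}, {0.0}

    # enumerate all optimal local alignments by traceback from every
    # optimal end cell; peptides are short so this stays tractable
    col_fracs: set[float] = set()
    min_fracs: set[float] = set()

    def trace(i, j, mat, idents, length):
        val = {"M": M, "X": X, "Y": Y}[mat][i][j]
        if mat == "M":
            s = _B62[a[i - 1]][b[j - 1]]
            ident = idents + (1 if a[i - 1] == b[j - 1] else 0)
            prev = val - s
            if abs(prev) < 1e-9:  # alignment starts here
                col_fracs.add(ident / (length + 1))
                min_fracs.add(ident / min(n, m))
            for pmat, pval in (("M", M[i - 1][j - 1]), ("X", X[i - 1][j - 1]),
                               ("Y", Y[i - 1][j - 1])):
                if pval > 0 and abs(pval - prev) < 1e-9:
                    trace(i - 1, j - 1, pmat, ident, length + 1)
        elif mat == "X":
            if abs(M[i - 1][j] - gap_open - val) < 1e-9:
                trace(i - 1, j, "M", idents, length + 1)
            if abs(X[i - 1][j] - gap_extend - val) < 1e-9:
                trace(i - 1, j, "X", idents, length + 1)
        else:
            if abs(M[i][j - 1] - gap_open - val) < 1e-9:
                trace(i, j - 1, "M", idents, length + 1)
            if abs(Y[i][j - 1] - gap_extend - val) < 1e-9:
                trace(i, j - 1, "Y", idents, length + 1)

    for i in range(1, n + 1):
        for j in range(1, m + 1):
            for mat, table in (("M", M), ("X", X), ("Y", Y)):
                if abs(table[i][j] - best) < 1e-9:
                    trace(i, j, mat, 0, 0)
    return best, col_fracs, min_fracs


# ---------------------------------------------------------------- graphs


def graph_density(nodes, edges) -> float:
    n = len(nodes)
    return 0.0 if n < 2 else 2 * len(edges) / (n * (n - 1))


def local_clustering(nodes, adj) -> dict:
    out = {}
    for u in nodes:
        neigh = sorted(adj[u])
        k = len(neigh)
        if k < 2:
            out[u] = 0.0
            continue
        links = sum(
            1 for x, y in itertools.combinations(neigh, 2) if y in adj[x]
        )
        out[u] = 2 * links / (k * (k - 1))
    return out


def all_shortest_paths(nodes, adj):
    """Hop distances and shortest-path counts by explicit path enumeration
    (BFS layer expansion, no networkx)."""
    dist = {u: {u: 0} for u in nodes}
    for u in nodes:
        frontier = [u]
        seen = {u}
        d = 0
        while frontier:
            d += 1
            nxt = []
            for v in frontier:
                for w in adj[v]:
                    if w not in seen:
                        seen.add(w)
                        dist[u][w] = d
                        nxt.append(w)
            frontier = nxt
    return dist


def count_shortest_paths(adj, s, t, dist):
    if s == t:
        return 1
    if t not in dist[s]:
        return 0
    total = 0
    for v in adj[t]:
        if v in dist[s] and dist[s][v] == dist[s][t] - 1:
            total += count_shortest_paths(adj, s, v, dist)
    return total


def brute_betweenness(nodes, adj) -> dict:
    dist = all_shortest_paths(nodes, adj)
    bc = {u: 0.0 for u in nodes}
    for s, t in itertools.combinations(nodes, 2):
        if t not in dist[s]:
            continue
        n_st = count_shortest_paths(adj, s, t, dist)
        for v in nodes:
            if v in (s, t):
                continue
            if (
                v in dist[s]
                and t in dist[v]
                and dist[s][v] + dist[v][t] == dist[s][t]
            ):
                n_through = count_shortest_paths(adj, s, v, dist) * count_shortest_paths(
                    adj, v, t, dist
                )
                bc[v] += n_through / n_st
    return bc


def brute_harmonic(nodes, adj) -> dict:
    dist = all_shortest_paths(nodes, adj)
    return {
        u: sum(1.0 / dist[v][u] for v in nodes if v != u and u in dist[v])
        for u in nodes
    }


def brute_diameter(nodes, adj) -> int:
    dist = all_shortest_paths(nodes, adj)
    comps = []
    unvisited = set(nodes)
    while unvisited:
        u = next(iter(unvisited))
        comp = set(dist[u]) & unvisited
        comps.append(comp)
        unvisited -= comp
    largest = max(comps, key=len)
    return max(
        (dist[u][v] for u in largest for v in largest if v in dist[u]), default=0
    )


def brute_hub_bridge(nodes, adj, labels) -> dict:
    sizes = {}
    for c in labels.values():
        sizes[c] = sizes.get(c, 0) + 1
    out = {}
    for u in nodes:
        intra = [v for v in adj[u] if labels[v] == labels[u]]
        inter = [v for v in adj[u] if labels[v] != labels[u]]
        out[u] = sizes[labels[u]] * len(intra) + len({labels[v] for v in inter}) * len(inter)
    return out


def brute_modularity(nodes, edges, labels) -> float:
    m = len(edges)
    if m == 0:
        return 0.0
    deg = {u: 0 for u in nodes}
    for u, v in edges:
        deg[u] += 1
        deg[v] += 1
    q = 0.0
    comms = set(labels.values())
    for c in comms:
        members = {u for u in nodes if labels[u] == c}
        e_c = sum(1 for u, v in edges if u in members and v in members)
        d_c = sum(deg[u] for u in members)
        q += e_c / m - (d_c / (2 * m)) ** 2
    return q


# ------------------------------------------------------------- statistics


def brute_metrics(tp, tn, fp, fn):
    """Independent coding of the eight confusion-matrix statistics."""
    total = tp + tn + fp + fn
    ac = (tp + tn) / total
    pc = ((tp + fp) * (tp + fn) + (fn + tn) * (fp + tn)) / total**2
    kappa = (ac - pc) / (1 - pc) if pc != 1 else 0.0
    den = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    mcc = (tp * tn - fp * fn) / math.sqrt(den) if den else 0.0
    return {
        "ac": ac,
        "kappa": kappa,
        "sn": tp / (tp + fn) if tp + fn else None,
        "sp": tn / (tn + fp) if tn + fp else None,
        "p_pos": tp / (tp + fp) if tp + fp else None,
        "p_neg": tn / (tn + fn) if tn + fn else None,
        "mcc": mcc,
        "far_percent": 100 * fp / (fp + tn) if fp + tn else None,
    }
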