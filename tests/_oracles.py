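"""Independent brute-force oracles used across the test suite.

Everything here is deliberately naive — Floyd–Warshall distances, explicit
enumeration of shortest paths, direct step-up scans — and shares no code
with the package implementation it checks.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np


def floyd_warshall(n: int, edges: set[frozenset]) -> np.ndarray:
    d = np.full((n, n), np.inf)
    np.fill_diagonal(d, 0.0)
    for e in edges:
        i, j = sorted(e)
        d[i, j] = d[j, i] = 1.0
    for k in range(n):
        d = np.minimum(d, d[:, [k]] + d[[k], :])
    return d


def all_shortest_paths(adj: dict, s: int, t: int, d: np.ndarray) -> list[list[int]]:
    """Enumerate every shortest s-t path by depth-first descent on distances."""
    if not np.isfinite(d[s, t]):
        return []
    if s == t:
        return [[s]]
    paths = []
    for u in adj[s]:
        if d[u, t] == d[s, t] - 1:
            for rest in all_shortest_paths(adj, u, t, d):
                paths.append([s] + rest)
    return paths


def graph_attributes_bruteforce(n: int, edges: set[frozenset]) -> dict:
    """All node and edge attributes of an unweighted graph, by definition."""
    adj = {i: {j for j in range(n) if frozenset({i, j}) in edges} for i in range(n)}
    d = floyd_warshall(n, edges)

    # components
    comp = [-1] * n
    cid = 0
    for i in range(n):
        if comp[i] == -1:
            for j in range(n):
                if np.isfinite(d[i, j]):
                    comp[j] = cid
            cid += 1
    comp_nodes = {c: [i for i in range(n) if comp[i] == c] for c in range(cid)}

    nodes = {}
    for v in range(n):
        deg = len(adj[v])
        reach = [u for u in range(n) if u != v and np.isfinite(d[v, u])]
        nc = float(np.mean([len(adj[u]) for u in adj[v]])) if deg else np.nan
        if reach:
            dist = np.array([d[v, u] for u in reach])
            aspl = dist.mean()
            clo = len(reach) / dist.sum()
            ecc = dist.max()
            members = comp_nodes[comp[v]]
            diam = max(
                d[a, b] for a in members for b in members if np.isfinite(d[a, b])
            )
            radial = sum(diam + 1 - d[v, u] for u in reach) / (len(members) - 1)
        else:
            aspl = clo = ecc = radial = np.nan
        if deg >= 2:
            tri = sum(1 for a, b in combinations(sorted(adj[v]), 2)
                      if frozenset({a, b}) in edges)
            clust = 2 * tri / (deg * (deg - 1))
        else:
            clust = 0.0
        nodes[v] = {
            "degree": deg,
            "neighbor_connectivity": nc,
            "avg_shortest_path_length": aspl,
            "closeness": clo,
            "clustering": clust,
            "eccentricity": ecc,
            "radiality": radial,
        }

    edge_btw = {e: 0.0 for e in edges}
    for s, t in combinations(range(n), 2):
        paths = all_shortest_paths(adj, s, t, d)
        if not paths:
            continue
        for path in paths:
            for a, b in zip(path, path[1:]):
                edge_btw[frozenset({a, b})] += 1.0 / len(paths)
    return {"nodes": nodes, "edge_betweenness": edge_btw}


def random_graph(n: int, p: float, rng: np.random.Generator) -> set[frozenset]:
    return {
        frozenset({i, j})
        for i, j in combinations(range(n), 2)
        if rng.random() < p
    }


def all_connected_graphs(n: int):
    """Yield the edge sets of every connected labelled graph on n nodes."""
    pairs = list(combinations(range(n), 2))
    for mask in range(1 << len(pairs)):
        edges = {frozenset(pairs[k]) for k in range(len(pairs)) if mask >> k & 1}
        d = floyd_warshall(n, edges)
        if np.all(np.isfinite(d)):
            yield edges


def bh_stepup_scan(p: np.ndarray, alpha: float) -> np.ndarray:
    """Textbook BH: reject H_(1..k*) where k* = max{k : p_(k) <= k/m alpha}."""
    m = len(p)
    order = np.argsort(p, kind="stable")
    sorted_p = p[order]
    kstar = 0
    for k in range(1, m + 1):
        if sorted_p[k - 1] <= k / m * alpha:
            kstar = k
    reject = np.zeros(m, dtype=bool)
    reject[order[:kstar]] = True
    return reject
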