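"""Independent brute-force oracles for small graphs.

Everything here is deliberately naive: Floyd–Warshall all-pairs
distances and exhaustive shortest-path enumeration, with no use of
networkx, so the production metrics have a genuinely independent
reference on graphs small enough to enumerate.
"""

from __future__ import annotations

import math


def floyd_warshall(nodes, edges):
    """All-pairs shortest-path distances; math.inf where unreachable."""
    dist = {u: {v: (0 if u == v else math.inf) for v in nodes} for u in nodes}
    for u, v in edges:
        dist[u][v] = 1
        dist[v][u] = 1
    for k in nodes:
        for i in nodes:
            dik = dist[i][k]
            if dik == math.inf:
                continue
            for j in nodes:
                alt = dik + dist[k][j]
                if alt < dist[i][j]:
                    dist[i][j] = alt
    return dist


def _enumerate_shortest_paths(adj, dist, s, t):
    """All shortest s-t paths as node tuples (DFS pruned by distance)."""
    target_len = dist[s][t]
    if target_len == math.inf:
        return []
    paths = []

    def walk(node, trail):
        if node == t:
            paths.append(tuple(trail))
            return
        for nb in adj[node]:
            if dist[nb][t] == dist[node][t] - 1:
                walk(nb, trail + [nb])

    walk(s, [s])
    return paths


def brute_force_metrics(nodes, edges):
    """degree / betweenness / corrected closeness / mean geodesic, per node.

    Betweenness is the fraction of shortest paths between every other
    unordered pair passing through the node, normalized by
    (n-1)(n-2)/2. Closeness is (r/sum d) * (r/(n-1)) over the node's r
    reachable peers. Mean geodesic distance is NaN for isolated nodes.
    """
    nodes = list(nodes)
    n = len(nodes)
    adj = {u: set() for u in nodes}
    for u, v in edges:
        adj[u].add(v)
        adj[v].add(u)
    dist = floyd_warshall(nodes, edges)

    betweenness = {u: 0.0 for u in nodes}
    for i, s in enumerate(nodes):
        for t in nodes[i + 1:]:
            paths = _enumerate_shortest_paths(adj, dist, s, t)
            if not paths:
                continue
            for v in nodes:
                if v in (s, t):
                    continue
                through = sum(1 for p in paths if v in p)
                betweenness[v] += through / len(paths)
    scale = (n - 1) * (n - 2) / 2
    if scale > 0:
        for v in nodes:
            betweenness[v] /= scale

    out = {}
    for u in nodes:
        finite = [dist[u][v] for v in nodes if v != u and dist[u][v] < math.inf]
        r = len(finite)
        total = sum(finite)
        closeness = (r / total) * (r / (n - 1)) if total > 0 and n > 1 else 0.0
        out[u] = {
            "degree": len(adj[u]),
            "betweenness": betweenness[u],
            "closeness": closeness,
            "avg_path_length": total / r if r else float("nan"),
        }
    return out


def random_graph(rng, n_max=8):
    """A random small graph (possibly disconnected, possibly with isolates)."""
    n = int(rng.integers(2, n_max + 1))
    p = float(rng.uniform(0.1, 0.8))
    nodes = list(range(n))
    edges = [(i, j) for i in nodes for j in nodes[i + 1:] if rng.random() < p]
    return nodes, edges
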