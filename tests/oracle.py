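"""Independent brute-force centrality oracle for small graphs.

Pure-Python reference implementations that enumerate every shortest path
explicitly.  Deliberately naive (exponential in the worst case) and entirely
separate from the package's vectorized engine; intended for graphs of at
most a dozen nodes.
"""

from __future__ import annotations

from collections import deque


def adjacency(graph) -> dict:
    """node -> sorted neighbor list (sorted by str, the pinned id order)."""
    return {v: sorted(graph.neighbors(v), key=str) for v in graph.nodes}


def bfs_distances(adj: dict, source) -> dict:
    dist = {source: 0}
    queue = deque([source])
    while queue:
        u = queue.popleft()
        for w in adj[u]:
            if w not in dist:
                dist[w] = dist[u] + 1
                queue.append(w)
    return dist


def enumerate_shortest_paths(adj: dict, dist_s: dict, s, t) -> list:
    """All shortest s-t paths as node lists, by explicit backtracking."""
    if t not in dist_s:
        return []
    if t == s:
        return [[s]]
    paths = []
    for u in adj[t]:
        if dist_s.get(u, -2) == dist_s[t] - 1:
            paths.extend(p + [t] for p in enumerate_shortest_paths(adj, dist_s, s, u))
    return paths


def degree(graph) -> dict:
    return {v: len(list(graph.neighbors(v))) for v in graph.nodes}


def betweenness_and_stress(graph) -> tuple[dict, dict]:
    """Fraction (betweenness) and count (stress) of shortest paths through v."""
    adj = adjacency(graph)
    nodes = list(graph.nodes)
    bet = {v: 0.0 for v in nodes}
    stress = {v: 0 for v in nodes}
    for i, s in enumerate(nodes):
        dist_s = bfs_distances(adj, s)
        for t in nodes[i + 1:]:
            if t == s or t not in dist_s:
                continue
            paths = enumerate_shortest_paths(adj, dist_s, s, t)
            for v in nodes:
                if v in (s, t):
                    continue
                through = sum(1 for p in paths if v in p)
                if through:
                    bet[v] += through / len(paths)
                    stress[v] += through
    return bet, stress


def harmonic_closeness(graph) -> dict:
    adj = adjacency(graph)
    out = {}
    for v in graph.nodes:
        dist = bfs_distances(adj, v)
        out[v] = sum(1.0 / d for w, d in dist.items() if w != v)
    return out


def eccentricity(graph) -> dict:
    adj = adjacency(graph)
    return {v: max(bfs_distances(adj, v).values()) for v in graph.nodes}


def radiality(graph) -> dict:
    adj = adjacency(graph)
    out = {}
    comps = _components(adj)
    for comp in comps:
        if len(comp) == 1:
            out[next(iter(comp))] = 0.0
            continue
        dist = {v: bfs_distances(adj, v) for v in comp}
        diam = max(max(d.values()) for d in dist.values())
        for v in comp:
            out[v] = sum(diam + 1 - dist[v][w] for w in comp if w != v) / (len(comp) - 1)
    return out


def bottleneck(graph) -> dict:
    """Roots whose deterministic BFS tree routes > |C|/4 of its paths via v.

    The tree parent of each node is its lexicographically smallest (by str)
    neighbor one hop closer to the root — the same pinned convention the
    package uses — but containment is counted by explicitly walking every
    node's tree path back to the root.
    """
    adj = adjacency(graph)
    out = {v: 0 for v in graph.nodes}
    for comp in _components(adj):
        quarter = len(comp) / 4.0
        for s in comp:
            dist_s = bfs_distances(adj, s)
            parent = {}
            for v in comp:
                if v == s:
                    continue
                parent[v] = min((u for u in adj[v] if dist_s[u] == dist_s[v] - 1),
                                key=str)
            contains = {v: 0 for v in comp}
            for t in comp:
                if t == s:
                    continue
                node = t
                while node != s:
                    contains[node] += 1
                    node = parent[node]
            for v in comp:
                if v != s and contains[v] > quarter:
                    out[v] += 1
    return out


def _components(adj: dict) -> list[set]:
    seen: set = set()
    comps = []
    for v in adj:
        if v in seen:
            continue
        comp = set(bfs_distances(adj, v))
        seen |= comp
        comps.append(comp)
    return comps
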