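"""Independent brute-force oracles used to validate the implementation.

Everything here is written from first principles (plain BFS / enumeration),
deliberately avoiding the graph and stats libraries the package itself
uses for the corresponding computation.
"""

from __future__ import annotations

from itertools import combinations
from math import comb


def bfs_distances(adj: dict, source):
    dist = {source: 0}
    frontier = [source]
    while frontier:
        nxt = []
        for u in frontier:
            for v in adj[u]:
                if v not in dist:
                    dist[v] = dist[u] + 1
                    nxt.append(v)
        frontier = nxt
    return dist


def enumerate_shortest_paths(adj: dict, s, t):
    """All shortest s-t paths, by depth-limited search along the BFS DAG."""
    dist = bfs_distances(adj, s)
    if t not in dist:
        return []
    paths = []

    def extend(path):
        u = path[-1]
        if u == t:
            paths.append(list(path))
            return
        for v in adj[u]:
            if dist.get(v) == dist[u] + 1 and dist[v] <= dist.get(t, -1):
                path.append(v)
                extend(path)
                path.pop()

    extend([s])
    return [p for p in paths if len(p) - 1 == dist[t]]


def brute_force_betweenness(adj: dict) -> dict:
    """Unnormalized pair-count betweenness via explicit path enumeration."""
    nodes = sorted(adj)
    b = {v: 0.0 for v in nodes}
    for s, t in combinations(nodes, 2):
        paths = enumerate_shortest_paths(adj, s, t)
        if not paths:
            continue
        sigma = len(paths)
        for v in nodes:
            if v in (s, t):
                continue
            through = sum(1 for p in paths if v in p)
            b[v] += through / sigma
    return b


def brute_force_clustering(adj: dict) -> dict:
    """Fraction of connected neighbour pairs; 0 for degree < 2."""
    out = {}
    for v, nbrs in adj.items():
        k = len(nbrs)
        if k < 2:
            out[v] = 0.0
            continue
        connected = sum(1 for a, b in combinations(sorted(nbrs), 2) if b in adj[a])
        out[v] = connected / comb(k, 2)
    return out


def brute_force_degree(adj: dict) -> dict:
    return {v: len(nbrs) for v, nbrs in adj.items()}


def exact_rank_sum_p_greater(x, y) -> float:
    """One-sided (x greater) exact permutation p of the rank-sum statistic."""
    pooled = sorted(list(x) + list(y))
    # midranks
    ranks = []
    i = 0
    rank_of = {}
    values = list(x) + list(y)
    svals = sorted(values)
    while i < len(svals):
        j = i
        while j < len(svals) and svals[j] == svals[i]:
            j += 1
        mid = (i + 1 + j) / 2
        rank_of[svals[i]] = mid
        i = j
    r = [rank_of[v] for v in values]
    w_obs = sum(r[: len(x)])
    n = len(values)
    count = 0
    total = 0
    for idx in combinations(range(n), len(x)):
        total += 1
        if sum(r[i] for i in idx) >= w_obs - 1e-9:
            count += 1
    return count / total


def venn_partition_oracle(sets: dict) -> dict:
    """Subset-enumeration Venn counts: iterate every non-empty label subset."""
    labels = sorted(sets)
    out = {}
    for r in range(1, len(labels) + 1):
        for sub in combinations(labels, r):
            inside = set.intersection(*(set(sets[c]) for c in sub))
            outside = set().union(*(set(sets[c]) for c in labels if c not in sub), set())
            region = inside - outside
            if region:
                out[frozenset(sub)] = len(region)
    return out
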