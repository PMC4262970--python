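"""Independent brute-force oracles used to validate the implementations.

Everything here is written from the definitions, without reusing any code
path from the package: UPGMA cluster distances are recomputed as means
over original leaf pairs, the rank-sum null is enumerated exhaustively,
TOM is a literal triple loop, and tree distances come from a hand-rolled
breadth-first search.
"""

from itertools import combinations
from math import comb

import numpy as np


def upgma_merge_heights(D):
    """Naive O(n^3) average-linkage: distances recomputed from leaf pairs.

    Returns (heights, merges) where merges is a list of frozensets of the
    leaf members of each newly formed cluster.
    """
    D = np.asarray(D, dtype=float)
    n = D.shape[0]
    clusters = [frozenset([i]) for i in range(n)]
    heights, merges = [], []
    while len(clusters) > 1:
        best = None
        for a, b in combinations(range(len(clusters)), 2):
            d = np.mean([D[i, j] for i in clusters[a] for j in clusters[b]])
            if best is None or d < best[0]:
                best = (d, a, b)
        d, a, b = best
        merged = clusters[a] | clusters[b]
        clusters = [c for k, c in enumerate(clusters) if k not in (a, b)]
        clusters.append(merged)
        heights.append(d)
        merges.append(merged)
    return heights, merges


def wmw_exact_two_sided(x, y):
    """Two-sided rank-sum p by full enumeration of all rank assignments.

    Requires untied data.  U is counted as the number of (x, y) pairs with
    x > y; the two-sided p doubles the smaller tail (capped at 1), the
    convention for a symmetric discrete null.
    """
    x, y = list(x), list(y)
    n, m = len(x), len(y)
    pooled = sorted(x + y)
    assert len(set(pooled)) == n + m, "oracle requires untied samples"
    ranks = {v: r for r, v in enumerate(pooled, start=1)}
    u_obs = sum(ranks[v] for v in x) - n * (n + 1) // 2
    total = comb(n + m, n)
    all_ranks = range(1, n + m + 1)
    us = np.array([sum(c) - n * (n + 1) // 2 for c in combinations(all_ranks, n)])
    le = int((us <= u_obs).sum())
    ge = int((us >= u_obs).sum())
    return u_obs, min(1.0, 2.0 * min(le, ge) / total)


def wmw_exact_distribution(n, m):
    """Null counts of U for sample sizes (n, m), by enumeration."""
    all_ranks = range(1, n + m + 1)
    us = [sum(c) - n * (n + 1) // 2 for c in combinations(all_ranks, n)]
    return np.bincount(us, minlength=n * m + 1)


def bh_step_up(p):
    """Literal BH step-up from the definition, via sorted scan."""
    p = list(map(float, p))
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    adj = [None] * m
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * m / rank)
        adj[i] = min(1.0, running)
    return adj


def tom_triple_loop(a):
    """Topological overlap by the definition, one entry at a time."""
    a = np.asarray(a, dtype=float)
    n = a.shape[0]
    k = [sum(a[i, u] for u in range(n) if u != i) for i in range(n)]
    t = np.eye(n)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            l = sum(a[i, u] * a[u, j] for u in range(n) if u not in (i, j))
            t[i, j] = (l + a[i, j]) / (min(k[i], k[j]) + 1 - a[i, j])
    return t


def bfs_distances(edges, source):
    """Hop counts from source over an undirected edge list."""
    adj = {}
    for u, v in edges:
        adj.setdefault(u, set()).add(v)
        adj.setdefault(v, set()).add(u)
    dist = {source: 0}
    frontier = [source]
    while frontier:
        nxt = []
        for u in frontier:
            for v in adj.get(u, ()):
                if v not in dist:
                    dist[v] = dist[u] + 1
                    nxt.append(v)
        frontier = nxt
    return dist
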