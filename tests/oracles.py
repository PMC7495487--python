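"""Independent brute-force oracles used by unit and acceptance tests.

These deliberately avoid the library code paths they check: shortest
paths are enumerated with hand-written BFS and path counting, and the
hypergeometric tail is summed with exact rational arithmetic.
"""

from __future__ import annotations

from collections import deque
from fractions import Fraction
from itertools import combinations
from math import comb


def _bfs_counts(adj: dict, source):
    """Distances and shortest-path counts from one source via plain BFS."""
    dist = {source: 0}
    sigma = {source: 1}
    queue = deque([source])
    while queue:
        u = queue.popleft()
        for v in adj[u]:
            if v not in dist:
                dist[v] = dist[u] + 1
                sigma[v] = 0
                queue.append(v)
            if dist[v] == dist[u] + 1:
                sigma[v] += sigma[u]
    return dist, sigma


def brute_betweenness(graph) -> dict:
    """Normalized betweenness by explicit shortest-path enumeration.

    For every unordered pair (s, t) and interior node v, the fraction of
    shortest s-t paths through v is sigma(s,v)*sigma(v,t)/sigma(s,t) when
    d(s,v)+d(v,t)=d(s,t). Scaled by 2/((n-1)(n-2)) for n >= 3, else 0.
    """
    nodes = list(graph.nodes())
    n = len(nodes)
    adj = {v: sorted(graph.neighbors(v)) for v in nodes}
    bfs = {v: _bfs_counts(adj, v) for v in nodes}
    bet = {v: 0.0 for v in nodes}
    for s, t in combinations(nodes, 2):
        dist_s, sigma_s = bfs[s]
        if t not in dist_s:
            continue
        dist_t, sigma_t = bfs[t]
        d_st = dist_s[t]
        for v in nodes:
            if v == s or v == t or v not in dist_s or v not in dist_t:
                continue
            if dist_s[v] + dist_t[v] == d_st:
                bet[v] += sigma_s[v] * sigma_t[v] / sigma_s[t]
    scale = 2.0 / ((n - 1) * (n - 2)) if n >= 3 else 0.0
    return {v: b * scale for v, b in bet.items()}


def brute_closeness(graph) -> dict:
    """Wasserman-Faust closeness from all-pairs BFS distances."""
    nodes = list(graph.nodes())
    n = len(nodes)
    adj = {v: sorted(graph.neighbors(v)) for v in nodes}
    out = {}
    for v in nodes:
        dist, _ = _bfs_counts(adj, v)
        r = len(dist)  # size of v's component (self included)
        total = sum(dist.values())
        if r <= 1 or total == 0 or n == 1:
            out[v] = 0.0
        else:
            out[v] = ((r - 1) / (n - 1)) * ((r - 1) / total)
    return out


def hypergeom_tail_exact(k: int, K: int, n: int, N: int) -> Fraction:
    """P(X >= k) for X ~ Hypergeometric(N, K, n), exact rational sum."""
    num = sum(comb(K, i) * comb(N - K, n - i) for i in range(k, min(K, n) + 1))
    return Fraction(num, comb(N, n))
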