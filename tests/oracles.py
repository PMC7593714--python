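"""Independent brute-force oracles used to check the implementation.

Deliberately naive and self-contained: centralities from all-pairs BFS with
explicit shortest-path counting and exhaustive triangle enumeration (no
networkx), hypergeometric tails in exact integer/rational arithmetic (no
scipy), Welch's test from its closed form, and BH step-up by hand.
"""

from __future__ import annotations

import math
from collections import deque
from fractions import Fraction


def _bfs(adj: dict, s):
    """Distances and shortest-path counts from s."""
    dist = {s: 0}
    sigma = {s: 1}
    q = deque([s])
    while q:
        v = q.popleft()
        for w in adj[v]:
            if w not in dist:
                dist[w] = dist[v] + 1
                sigma[w] = 0
                q.append(w)
            if dist[w] == dist[v] + 1:
                sigma[w] += sigma[v]
    return dist, sigma


def brute_force_centralities(nodes, edges):
    """dc, bc, cc, nc, lac dicts for a simple undirected graph."""
    nodes = list(nodes)
    adj = {v: set() for v in nodes}
    for u, v in edges:
        if u != v:
            adj[u].add(v)
            adj[v].add(u)
    n = len(nodes)
    dc = {v: len(adj[v]) for v in nodes}

    dists, sigmas = {}, {}
    for s in nodes:
        dists[s], sigmas[s] = _bfs(adj, s)

    # betweenness: per unordered pair (s, t), fraction of shortest paths via v
    bc = {v: 0.0 for v in nodes}
    for i, s in enumerate(nodes):
        for t in nodes[i + 1 :]:
            if t not in dists[s]:
                continue
            d_st = dists[s][t]
            n_st = sigmas[s][t]
            for v in nodes:
                if v in (s, t) or v not in dists[s] or v not in dists[t]:
                    continue
                if dists[s][v] + dists[t][v] == d_st:
                    bc[v] += sigmas[s][v] * sigmas[t][v] / n_st

    # closeness with reachable-set size correction
    cc = {}
    for v in nodes:
        reach = [d for u, d in dists[v].items() if u != v]
        r, total = len(reach), sum(reach)
        cc[v] = (r / total) * (r / (n - 1)) if r > 0 and total > 0 else 0.0

    # triangle counts per edge by exhaustive enumeration
    def z(u, v):
        return sum(1 for w in nodes if w in adj[u] and w in adj[v])

    nc = {}
    for v in nodes:
        total = 0.0
        for u in adj[v]:
            den = min(dc[u] - 1, dc[v] - 1)
            if den > 0:
                total += z(u, v) / den
        nc[v] = total

    lac = {}
    for v in nodes:
        nbrs = adj[v]
        if not nbrs:
            lac[v] = 0.0
            continue
        induced_deg = {u: sum(1 for w in nbrs if w in adj[u]) for u in nbrs}
        lac[v] = sum(induced_deg.values()) / len(nbrs)

    return dc, bc, cc, nc, lac


def hypergeom_pmf_exact(N: int, K: int, n: int) -> list[Fraction]:
    """Exact P(X = k) for k = 0..n (zero outside the support)."""
    denom = math.comb(N, n)
    return [Fraction(math.comb(K, k) * math.comb(N - K, n - k), denom) for k in range(n + 1)]


def hypergeom_tail_exact(k: int, N: int, K: int, n: int) -> Fraction:
    """Exact upper tail P(X >= k)."""
    if k <= 0:
        return Fraction(1)
    denom = math.comb(N, n)
    num = sum(math.comb(K, j) * math.comb(N - K, n - j) for j in range(k, min(K, n) + 1))
    return Fraction(num, denom)


def welch_oracle(a, b):
    """(t, two-sided p) from the closed-form Welch statistic and df."""
    from scipy.stats import t as t_dist

    na, nb = len(a), len(b)
    ma, mb = sum(a) / na, sum(b) / nb
    va = sum((x - ma) ** 2 for x in a) / (na - 1)
    vb = sum((x - mb) ** 2 for x in b) / (nb - 1)
    se2 = va / na + vb / nb
    t = (mb - ma) / math.sqrt(se2)
    df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    return t, 2.0 * float(t_dist.sf(abs(t), df))


def bh_oracle(p: list[float]) -> list[float]:
    """Step-up BH: m*p_(i)/i with cumulative minimum from the largest rank."""
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    adj = [0.0] * m
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, m * p[i] / rank)
        adj[i] = running
    return adj
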