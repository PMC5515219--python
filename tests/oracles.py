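"""Independent brute-force oracles used to cross-check the implementation.

Everything here is deliberately naive: BFS sigma-counting for
betweenness, explicit tail summation for the hypergeometric test,
exhaustive sign-flip enumeration for the Wilcoxon signed-rank null,
and the textbook step-up formula for Benjamini-Hochberg. None of it
shares code with the package.
"""

from __future__ import annotations

import itertools
from collections import deque
from math import comb


def bfs_sigma(adj: dict, source):
    """Distances and shortest-path counts from one source by plain BFS."""
    dist = {source: 0}
    sigma = {source: 1}
    q = deque([source])
    while q:
        u = q.popleft()
        for v in adj[u]:
            if v not in dist:
                dist[v] = dist[u] + 1
                sigma[v] = 0
                q.append(v)
            if dist[v] == dist[u] + 1:
                sigma[v] += sigma[u]
    return dist, sigma


def brute_betweenness(nodes, edges):
    """Unnormalized betweenness over unordered pairs, endpoints excluded.

    Uses the pair-split identity sigma_st(n) = sigma_sn * sigma_nt when
    d(s,n) + d(n,t) = d(s,t), with sigma from independent per-source BFS.
    """
    adj = {n: set() for n in nodes}
    for u, v in edges:
        if u != v:
            adj[u].add(v)
            adj[v].add(u)
    info = {s: bfs_sigma(adj, s) for s in nodes}
    bet = {n: 0.0 for n in nodes}
    node_list = sorted(nodes)
    for i, s in enumerate(node_list):
        dist_s, sig_s = info[s]
        for t in node_list[i + 1 :]:
            if t not in dist_s:
                continue
            d_st = dist_s[t]
            sig_st = sig_s[t]
            for n in node_list:
                if n == s or n == t or n not in dist_s:
                    continue
                dist_n, sig_n = info[n]
                if t in dist_n and dist_s[n] + dist_n[t] == d_st:
                    bet[n] += sig_s[n] * sig_n[t] / sig_st
    return bet


def hypergeom_upper_tail(a: int, n_sel: int, n_in: int, n_total: int) -> float:
    """P(X >= a) for X ~ Hypergeom(N=n_total, K=n_in, n=n_sel)."""
    denom = comb(n_total, n_sel)
    upper = min(n_sel, n_in)
    return sum(
        comb(n_in, k) * comb(n_total - n_in, n_sel - k) for k in range(a, upper + 1)
    ) / denom


def wilcoxon_exact_two_sided(diffs) -> float:
    """Exact two-sided signed-rank p by enumerating all sign assignments.

    Assumes no zero differences and no tied absolute values (the cases
    where the exact null distribution is unambiguous).
    """
    diffs = list(diffs)
    n = len(diffs)
    abs_sorted = sorted(range(n), key=lambda i: abs(diffs[i]))
    ranks = [0] * n
    for r, i in enumerate(abs_sorted, start=1):
        ranks[i] = r
    w_plus = sum(r for d, r in zip(diffs, ranks) if d > 0)
    w_minus = sum(r for d, r in zip(diffs, ranks) if d < 0)
    w_obs = min(w_plus, w_minus)
    count = 0
    for signs in itertools.product((0, 1), repeat=n):
        wp = sum(r for s, r in zip(signs, ranks) if s)
        wm = sum(ranks) - wp
        if min(wp, wm) <= w_obs:
            count += 1
    return min(1.0, count / 2**n)


def bh_adjust(pvals):
    """Benjamini-Hochberg step-up adjusted p-values (textbook formula)."""
    m = len(pvals)
    order = sorted(range(m), key=lambda i: pvals[i])
    adjusted = [0.0] * m
    prev = 1.0
    for rank_from_end, idx in enumerate(reversed(order)):
        rank = m - rank_from_end
        val = min(prev, pvals[idx] * m / rank)
        adjusted[idx] = val
        prev = val
    return adjusted


def partition_by_pair_set(pair_sets: dict) -> set[frozenset]:
    """Brute-force partition of keys into groups with equal pair-sets."""
    groups: dict[frozenset, set] = {}
    for ko, ps in pair_sets.items():
        groups.setdefault(frozenset(ps), set()).add(ko)
    return {frozenset(v) for v in groups.values()}
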