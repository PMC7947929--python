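"""Independent brute-force oracles for graph metrics and statistics.

Everything here is written from first principles (Floyd-Warshall distances,
explicit shortest-path enumeration, step-up inequalities) and deliberately
shares no code path with the package implementation.
"""

from __future__ import annotations

import numpy as np

INF = float("inf")


def floyd_warshall(adj: np.ndarray) -> np.ndarray:
    n = adj.shape[0]
    d = np.full((n, n), INF)
    np.fill_diagonal(d, 0.0)
    d[adj.astype(bool)] = 1.0
    for k in range(n):
        for i in range(n):
            for j in range(n):
                if d[i, k] + d[k, j] < d[i, j]:
                    d[i, j] = d[i, k] + d[k, j]
    return d


def global_efficiency(adj: np.ndarray) -> float:
    n = adj.shape[0]
    d = floyd_warshall(adj)
    total = 0.0
    for i in range(n):
        for j in range(n):
            if i != j and d[i, j] < INF:
                total += 1.0 / d[i, j]
    return total / (n * (n - 1))


def nodal_global_efficiency(adj: np.ndarray, i: int) -> float:
    n = adj.shape[0]
    d = floyd_warshall(adj)
    return sum(1.0 / d[i, j] for j in range(n) if j != i and d[i, j] < INF) / (n - 1)


def neighbor_subgraph(adj: np.ndarray, i: int) -> np.ndarray:
    nbrs = [j for j in range(adj.shape[0]) if adj[i, j]]
    return adj[np.ix_(nbrs, nbrs)]


def nodal_local_efficiency(adj: np.ndarray, i: int) -> float:
    sub = neighbor_subgraph(adj, i)
    m = sub.shape[0]
    if m < 2:
        return 0.0
    d = floyd_warshall(sub)
    total = sum(
        1.0 / d[a, b]
        for a in range(m) for b in range(m)
        if a != b and d[a, b] < INF
    )
    return total / (m * (m - 1))


def local_efficiency(adj: np.ndarray) -> float:
    n = adj.shape[0]
    return sum(nodal_local_efficiency(adj, i) for i in range(n)) / n


def _count_shortest_paths(adj, d, s, t):
    """Enumerate all shortest s-t paths; return (count, interior visit counts)."""
    n = adj.shape[0]
    interior = np.zeros(n)
    if d[s, t] == INF or s == t:
        return 0, interior
    count = 0
    stack = [(s, [s])]
    while stack:
        v, path = stack.pop()
        if v == t:
            count += 1
            for node in path[1:-1]:
                interior[node] += 1
            continue
        for u in range(n):
            if adj[v, u] and d[u, t] == d[v, t] - 1:
                stack.append((u, path + [u]))
    return count, interior


def betweenness(adj: np.ndarray) -> np.ndarray:
    """Unnormalized betweenness by explicit shortest-path enumeration."""
    n = adj.shape[0]
    d = floyd_warshall(adj)
    bc = np.zeros(n)
    for s in range(n):
        for t in range(s + 1, n):
            sigma, interior = _count_shortest_paths(adj, d, s, t)
            if sigma > 0:
                bc += interior / sigma
    return bc


def clustering(adj: np.ndarray) -> np.ndarray:
    n = adj.shape[0]
    out = np.zeros(n)
    for i in range(n):
        nbrs = [j for j in range(n) if adj[i, j]]
        k = len(nbrs)
        if k < 2:
            continue
        links = sum(
            1 for a in range(k) for b in range(a + 1, k)
            if adj[nbrs[a], nbrs[b]]
        )
        out[i] = 2.0 * links / (k * (k - 1))
    return out


def characteristic_path_length(adj: np.ndarray) -> float:
    n = adj.shape[0]
    d = floyd_warshall(adj)
    vals = [d[i, j] for i in range(n) for j in range(n)
            if i != j and d[i, j] < INF]
    return float(np.mean(vals)) if vals else float("nan")


def bh_stepup(p_values, q):
    """Benjamini-Hochberg by direct step-up enumeration.

    Returns (adjusted q-values, reject booleans) in the input order.
    """
    p = np.asarray(p_values, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    sorted_p = p[order]
    k_max = 0
    for k in range(1, m + 1):  # largest k with p_(k) <= k*q/m
        if sorted_p[k - 1] <= k * q / m:
            k_max = k
    reject_sorted = np.array([k < k_max for k in range(m)])
    adj_sorted = np.empty(m)
    running = 1.0
    for k in range(m, 0, -1):  # enforce monotone adjusted values
        running = min(running, m * sorted_p[k - 1] / k)
        adj_sorted[k - 1] = running
    qvals = np.empty(m)
    reject = np.empty(m, dtype=bool)
    qvals[order] = adj_sorted
    reject[order] = reject_sorted
    return qvals, reject


def kruskal_h(samples):
    """Kruskal-Wallis H with tie correction, from the rank-sum formula."""
    pooled = np.concatenate(samples)
    n_tot = len(pooled)
    order = np.argsort(pooled, kind="stable")
    ranks = np.empty(n_tot)
    sorted_vals = pooled[order]
    i = 0
    while i < n_tot:
        j = i
        while j < n_tot and sorted_vals[j] == sorted_vals[i]:
            j += 1
        ranks[order[i:j]] = (i + j + 1) / 2.0  # average rank, 1-based
        i = j
    start = 0
    h = 0.0
    for s in samples:
        r = ranks[start:start + len(s)]
        h += len(s) * (r.mean() - (n_tot + 1) / 2.0) ** 2
        start += len(s)
    h *= 12.0 / (n_tot * (n_tot + 1))
    _, counts = np.unique(pooled, return_counts=True)
    tie_corr = 1.0 - np.sum(counts**3 - counts) / (n_tot**3 - n_tot)
    return h / tie_corr


def spearman_rho(x, y):
    """Spearman via the all-pairs definition: Pearson on average ranks."""
    def avg_rank(v):
        v = np.asarray(v, dtype=float)
        r = np.empty(len(v))
        for i, vi in enumerate(v):
            less = np.sum(v < vi)
            equal = np.sum(v == vi)
            r[i] = less + (equal + 1) / 2.0
        return r

    rx, ry = avg_rank(x), avg_rank(y)
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    denom = np.sqrt((rx @ rx) * (ry @ ry))
    return float((rx @ ry) / denom) if denom > 0 else 0.0
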