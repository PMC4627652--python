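"""Independent brute-force oracles used to validate the fast implementations.

Everything here is written for transparency, not speed: Floyd–Warshall
distances, explicit shortest-path enumeration for betweenness, literal
neighbor-subgraph reconstruction for local efficiency, a direct double-sum
for modularity, exhaustive search over all set partitions, and a
threshold-by-threshold Benjamini–Hochberg check.
"""

from __future__ import annotations

import itertools

import numpy as np


def floyd_warshall(adj: np.ndarray) -> np.ndarray:
    n = adj.shape[0]
    d = np.where(adj > 0, 1.0, np.inf)
    np.fill_diagonal(d, 0.0)
    for k in range(n):
        for i in range(n):
            for j in range(n):
                if d[i, k] + d[k, j] < d[i, j]:
                    d[i, j] = d[i, k] + d[k, j]
    return d


def brute_global_efficiency(adj: np.ndarray) -> float:
    n = adj.shape[0]
    if n < 2:
        return 0.0
    d = floyd_warshall(adj)
    total = 0.0
    for i in range(n):
        for j in range(n):
            if i != j and np.isfinite(d[i, j]):
                total += 1.0 / d[i, j]
    return total / (n * (n - 1))


def brute_nodal_efficiency(adj: np.ndarray) -> np.ndarray:
    n = adj.shape[0]
    d = floyd_warshall(adj)
    out = np.zeros(n)
    for i in range(n):
        for j in range(n):
            if i != j and np.isfinite(d[i, j]):
                out[i] += 1.0 / d[i, j]
    return out / (n - 1)


def brute_local_efficiency(adj: np.ndarray) -> float:
    n = adj.shape[0]
    total = 0.0
    for i in range(n):
        nbrs = [j for j in range(n) if adj[i, j]]
        if len(nbrs) < 2:
            continue
        sub = adj[np.ix_(nbrs, nbrs)]
        total += brute_global_efficiency(sub)
    return total / n


def _all_shortest_paths(adj: np.ndarray, src: int, dst: int) -> list[list[int]]:
    """Every shortest src-dst path, by BFS layering then backtracking."""
    n = adj.shape[0]
    dist = {src: 0}
    frontier = [src]
    while frontier and dst not in dist:
        nxt = []
        for u in frontier:
            for v in range(n):
                if adj[u, v] and v not in dist:
                    dist[v] = dist[u] + 1
                    nxt.append(v)
        frontier = nxt
    if dst not in dist:
        return []

    paths: list[list[int]] = []

    def back(node: int, acc: list[int]) -> None:
        if node == src:
            paths.append([src] + acc)
            return
        for u in range(n):
            if adj[u, node] and dist.get(u, -1) == dist[node] - 1:
                back(u, [node] + acc)

    back(dst, [])
    return paths


def brute_betweenness(adj: np.ndarray) -> np.ndarray:
    """B_i summed over unordered pairs via explicit path enumeration."""
    n = adj.shape[0]
    b = np.zeros(n)
    for j, k in itertools.combinations(range(n), 2):
        paths = _all_shortest_paths(adj, j, k)
        if not paths:
            continue
        for path in paths:
            for node in path[1:-1]:
                b[node] += 1.0 / len(paths)
    return b


def brute_modularity(adj: np.ndarray, assignment: np.ndarray) -> float:
    n = adj.shape[0]
    k = adj.sum(axis=1).astype(float)
    two_e = k.sum()
    q = 0.0
    for i in range(n):
        for j in range(n):
            if assignment[i] == assignment[j]:
                q += adj[i, j] - k[i] * k[j] / two_e
    return q / two_e


def iter_set_partitions(n: int):
    """All partitions of range(n) as assignment vectors (restricted growth)."""
    a = [0] * n
    b = [0] * n  # b[i] = max(a[:i+1])

    while True:
        yield np.array(a)
        # next restricted growth string
        i = n - 1
        while i > 0 and a[i] == b[i - 1] + 1:
            i -= 1
        if i == 0:
            return
        a[i] += 1
        b[i] = max(b[i - 1], a[i])
        for j in range(i + 1, n):
            a[j] = 0
            b[j] = b[i]


def exhaustive_best_partition(adj: np.ndarray) -> tuple[float, np.ndarray]:
    best_q, best = -np.inf, None
    for assignment in iter_set_partitions(adj.shape[0]):
        q = brute_modularity(adj, assignment)
        if q > best_q + 1e-15:
            best_q, best = q, assignment.copy()
    return best_q, best


def bh_flags_exhaustive(pvals: np.ndarray, q: float) -> np.ndarray:
    """BH step-up by checking every candidate rejection threshold."""
    p = np.asarray(pvals, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    k_star = 0
    for rank, idx in enumerate(order, start=1):
        if p[idx] <= q * rank / m:
            k_star = rank
    flags = np.zeros(m, dtype=bool)
    flags[order[:k_star]] = True
    return flags


def random_graph(rng: np.random.Generator, n: int, p: float | None = None) -> np.ndarray:
    """Random simple undirected adjacency matrix (0/1, zero diagonal)."""
    if p is None:
        p = rng.uniform(0.15, 0.8)
    upper = np.triu(rng.random((n, n)) < p, k=1)
    return (upper | upper.T).astype(np.uint8)
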