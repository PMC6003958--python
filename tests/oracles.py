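"""Independent brute-force oracles used to cross-check the fast implementations.

Deliberately naive: explicit loops, closed forms and dense matrix algorithms
that share no code path with the package.
"""

from __future__ import annotations

import numpy as np


def pearson(x, y) -> float:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    xc, yc = x - x.mean(), y - y.mean()
    return float(np.sum(xc * yc) / np.sqrt(np.sum(xc ** 2) * np.sum(yc ** 2)))


def midranks(x) -> np.ndarray:
    """Average-rank-for-ties transform, by explicit enumeration."""
    x = np.asarray(x, dtype=float)
    out = np.empty(len(x))
    for i, v in enumerate(x):
        less = np.sum(x < v)
        equal = np.sum(x == v)
        out[i] = less + (equal + 1) / 2.0
    return out


def spearman(x, y) -> float:
    return pearson(midranks(x), midranks(y))


def ols_loglog(ks, counts) -> tuple[float, float]:
    """Closed-form OLS of log10 counts on log10 ks; returns (slope, r2)."""
    x = np.log10(np.asarray(ks, dtype=float))
    y = np.log10(np.asarray(counts, dtype=float))
    n = len(x)
    sx, sy = x.sum(), y.sum()
    sxx, sxy = np.sum(x * x), np.sum(x * y)
    slope = (n * sxy - sx * sy) / (n * sxx - sx ** 2)
    intercept = (sy - slope * sx) / n
    ss_res = float(np.sum((y - slope * x - intercept) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0 and ss_res < 1e-24 else 1.0 - ss_res / ss_tot
    return float(slope), r2


def adjacency_matrix(graph) -> tuple[list, np.ndarray]:
    nodes = sorted(graph.nodes, key=str)
    idx = {n: i for i, n in enumerate(nodes)}
    A = np.zeros((len(nodes), len(nodes)), dtype=bool)
    for u, v in graph.edges:
        A[idx[u], idx[v]] = A[idx[v], idx[u]] = True
    return nodes, A


def clustering_by_triangles(graph) -> float:
    """Mean local clustering over degree>=1 vertices via triangle enumeration."""
    nodes, A = adjacency_matrix(graph)
    vals = []
    for i in range(len(nodes)):
        nbrs = np.flatnonzero(A[i])
        k = len(nbrs)
        if k == 0:
            continue
        if k < 2:
            vals.append(0.0)
            continue
        tri = 0
        for a in range(k):
            for b in range(a + 1, k):
                if A[nbrs[a], nbrs[b]]:
                    tri += 1
        vals.append(tri / (k * (k - 1) / 2))
    if not vals:
        raise ValueError("no used vertices")
    return float(np.mean(vals))


def floyd_warshall_mean_path(graph) -> float:
    """Mean shortest path over connected pairs in the largest component."""
    nodes, A = adjacency_matrix(graph)
    n = len(nodes)
    D = np.full((n, n), np.inf)
    np.fill_diagonal(D, 0.0)
    D[A] = 1.0
    for k in range(n):
        D = np.minimum(D, D[:, k:k + 1] + D[k:k + 1, :])
    comps = union_find_components(graph)
    biggest = max(len(c) for c in comps)
    big = min((c for c in comps if len(c) == biggest),
              key=lambda c: min(map(str, c)))
    idx = {v: i for i, v in enumerate(nodes)}
    members = [idx[v] for v in big]
    if len(members) < 2:
        raise ValueError("largest component too small")
    total, count = 0.0, 0
    for a in range(len(members)):
        for b in range(a + 1, len(members)):
            total += D[members[a], members[b]]
            count += 1
    return total / count


def union_find_components(graph) -> list[set]:
    parent = {v: v for v in graph.nodes}

    def find(v):
        while parent[v] != v:
            parent[v] = parent[parent[v]]
            v = parent[v]
        return v

    for u, v in graph.edges:
        ru, rv = find(u), find(v)
        if ru != rv:
            parent[ru] = rv
    comps: dict = {}
    for v in graph.nodes:
        comps.setdefault(find(v), set()).add(v)
    return list(comps.values())
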