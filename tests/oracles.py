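"""Independent brute-force oracles used to validate the implementations.

Everything here is deliberately naive (triple loops, exhaustive
enumeration, literal definitions) and shares no code with the package.
"""

from __future__ import annotations

import numpy as np


def floyd_warshall(w: np.ndarray) -> np.ndarray:
    """All-pairs shortest distances with edge length 1/weight."""
    n = w.shape[0]
    d = np.full((n, n), np.inf)
    np.fill_diagonal(d, 0.0)
    for i in range(n):
        for j in range(n):
            if i != j and w[i, j] > 0:
                d[i, j] = 1.0 / w[i, j]
    for k in range(n):
        for i in range(n):
            for j in range(n):
                if d[i, k] + d[k, j] < d[i, j]:
                    d[i, j] = d[i, k] + d[k, j]
    return d


def path_length_mean(w: np.ndarray) -> float:
    d = floyd_warshall(w)
    vals = [d[i, j] for i in range(len(w)) for j in range(i + 1, len(w))]
    return float(np.mean(vals))


def efficiency_global(w: np.ndarray) -> float:
    d = floyd_warshall(w)
    vals = [1.0 / d[i, j] for i in range(len(w)) for j in range(i + 1, len(w))]
    return float(np.mean(vals))


def efficiency_nodal(w: np.ndarray) -> np.ndarray:
    d = floyd_warshall(w)
    n = len(w)
    return np.array([
        np.mean([1.0 / d[i, j] for j in range(n) if j != i]) for i in range(n)
    ])


def clustering_direct(w: np.ndarray) -> np.ndarray:
    """Onnela weighted clustering via explicit triangle loops."""
    n = w.shape[0]
    wn = w / w.max() if w.max() > 0 else w
    out = np.zeros(n)
    for i in range(n):
        nbrs = [j for j in range(n) if w[i, j] > 0]
        k = len(nbrs)
        if k < 2:
            continue
        s = 0.0
        for a in range(len(nbrs)):
            for b in range(a + 1, len(nbrs)):
                j, h = nbrs[a], nbrs[b]
                s += (wn[i, j] * wn[i, h] * wn[j, h]) ** (1.0 / 3.0)
        out[i] = 2.0 * s / (k * (k - 1))
    return out


def betweenness_exhaustive(w: np.ndarray, tol: float = 1e-9) -> np.ndarray:
    """Betweenness by enumerating every simple path between every pair."""
    n = w.shape[0]
    adj = [[j for j in range(n) if w[i, j] > 0] for i in range(n)]
    bc = np.zeros(n)
    for s in range(n):
        for t in range(s + 1, n):
            paths: list[tuple[float, list[int]]] = []

            def dfs(v: int, dist: float, path: list[int]) -> None:
                if v == t:
                    paths.append((dist, list(path)))
                    return
                for u in adj[v]:
                    if u not in path:
                        path.append(u)
                        dfs(u, dist + 1.0 / w[v, u], path)
                        path.pop()

            dfs(s, 0.0, [s])
            if not paths:
                continue
            dmin = min(p[0] for p in paths)
            shortest = [p[1] for p in paths if p[0] <= dmin + tol * max(1.0, dmin)]
            for p in shortest:
                for v in p[1:-1]:
                    bc[v] += 1.0 / len(shortest)
    return bc


def degree_count(w: np.ndarray) -> np.ndarray:
    return np.array([(w[i] > 0).sum() for i in range(len(w))])


def connected_union_find(w: np.ndarray) -> bool:
    n = w.shape[0]
    parent = list(range(n))

    def find(a):
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    for i in range(n):
        for j in range(i + 1, n):
            if w[i, j] > 0:
                parent[find(i)] = find(j)
    return len({find(i) for i in range(n)}) == 1


def bh_stepup(p: np.ndarray, alpha: float) -> np.ndarray:
    """Literal Benjamini-Hochberg: reject the k smallest p-values where k is
    the largest index with p_(k) <= k/m * alpha."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    k_max = 0
    for k in range(1, m + 1):
        if p[order[k - 1]] <= k * alpha / m:
            k_max = k
    reject = np.zeros(m, dtype=bool)
    reject[order[:k_max]] = True
    return reject


def ols_line(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """(slope, intercept, SEE) from the normal equations."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = len(x)
    sxx = ((x - x.mean()) ** 2).sum()
    sxy = ((x - x.mean()) * (y - y.mean())).sum()
    slope = sxy / sxx
    intercept = y.mean() - slope * x.mean()
    resid = y - intercept - slope * x
    see = float(np.sqrt((resid**2).sum() / (n - 2)))
    return float(slope), float(intercept), see


def random_connected_graph(rng: np.random.Generator, n: int,
                           p_edge: float = 0.4) -> np.ndarray:
    """Random symmetric weighted graph, guaranteed connected via a ring."""
    w = np.zeros((n, n))
    for i in range(n):
        j = (i + 1) % n
        wt = rng.uniform(0.2, 0.9)
        w[i, j] = w[j, i] = wt
    for i in range(n):
        for j in range(i + 2, n):
            if (i, j) != (0, n - 1) and rng.random() < p_edge:
                wt = rng.uniform(0.2, 0.9)
                w[i, j] = w[j, i] = wt
    return w
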