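"""Weighted graph-theory metrics for FA-weighted connectomes.

All path-based metrics use edge length = 1/weight, the standard convention
for FA-weighted structural networks (stronger connections are "shorter").
Small-worldness standardizes the empirical clustering coefficient and
characteristic path length against degree-preserving, weight-preserving
random rewirings (Maslov-Sneppen double-edge swaps):

    gamma = Cp / <Cp_null>,   lambda = Lp / <Lp_null>,   sigma = gamma / lambda

The weighted clustering coefficient is the Onnela geometric-mean-of-triangles
form computed on weights normalized by the network-wide maximum, so it is
invariant to a global rescaling of edge weights.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import shortest_path as _csgraph_shortest_path

from .connectome import ConnectivityMatrix, is_fully_connected

_TIE_TOL = 1e-12


class DisconnectedGraphError(ValueError):
    """Raised when a path-based metric is asked for a disconnected matrix."""


def _lengths(w: np.ndarray) -> np.ndarray:
    with np.errstate(divide="ignore"):
        ln = np.where(w > 0, 1.0 / np.where(w > 0, w, 1.0), np.inf)
    np.fill_diagonal(ln, 0.0)
    return ln


def shortest_path_lengths(m: ConnectivityMatrix) -> np.ndarray:
    """All-pairs weighted shortest-path distances (length = 1/weight)."""
    w = m.weights
    sparse = csr_matrix(np.where(w > 0, 1.0 / np.where(w > 0, w, 1.0), 0.0))
    d = _csgraph_shortest_path(sparse, method="D", directed=False)
    if np.isinf(d).any():
        raise DisconnectedGraphError(
            f"scan {m.scan_id!r}: disconnected matrix; apply the connectedness filter first"
        )
    return d


def characteristic_path_length(m: ConnectivityMatrix, d: np.ndarray | None = None) -> float:
    """Lp: mean shortest-path distance over unordered node pairs."""
    d = shortest_path_lengths(m) if d is None else d
    iu = np.triu_indices_from(d, k=1)
    return float(d[iu].mean())


def global_efficiency(m: ConnectivityMatrix, d: np.ndarray | None = None) -> float:
    """Eg: mean inverse shortest-path distance over unordered pairs."""
    d = shortest_path_lengths(m) if d is None else d
    iu = np.triu_indices_from(d, k=1)
    return float((1.0 / d[iu]).mean())


def nodal_efficiency(m: ConnectivityMatrix, d: np.ndarray | None = None) -> np.ndarray:
    """Ne(i): mean of 1/d(i,j) over j != i."""
    d = shortest_path_lengths(m) if d is None else d
    n = d.shape[0]
    inv = 1.0 / np.where(d > 0, d, np.inf)
    return inv.sum(axis=1) / (n - 1)


def clustering_coefficients(m: ConnectivityMatrix) -> tuple[float, np.ndarray]:
    """(Cp, NCp): Onnela weighted clustering on max-normalized weights.

    NCp(i) = (2 / (k_i (k_i - 1))) * sum_{j<h} (w'_ij w'_ih w'_jh)^(1/3)
    with w' = w / max(w); NCp(i) = 0 when degree k_i < 2.  Cp averages over
    all nodes so the denominator is constant across scans.
    """
    w = m.weights
    wmax = w.max()
    if wmax == 0:
        return 0.0, np.zeros(w.shape[0])
    cube = np.cbrt(w / wmax)
    k = (w > 0).sum(axis=1)
    tri = np.diagonal(cube @ cube @ cube)  # 2x the triangle sum per node
    denom = k * (k - 1)
    ncp = np.where(denom > 0, tri / np.where(denom > 0, denom, 1), 0.0)
    return float(ncp.mean()), ncp


def degree_centrality(m: ConnectivityMatrix) -> tuple[np.ndarray, float]:
    """Dc(i) = number of strictly-positive edges at node i; plus its mean."""
    dc = (m.weights > 0).sum(axis=1)
    return dc, float(dc.mean())


def betweenness_centrality(m: ConnectivityMatrix) -> np.ndarray:
    """Brandes betweenness over weighted shortest paths (length = 1/w).

    Counts each unordered source-target pair once; tied shortest paths split
    the contribution proportionally to path counts.
    """
    if not is_fully_connected(m):
        raise DisconnectedGraphError(f"scan {m.scan_id!r}: disconnected matrix")
    w = m.weights
    n = w.shape[0]
    nbrs = [np.nonzero(w[i] > 0)[0] for i in range(n)]
    lens = [1.0 / w[i, nbrs[i]] for i in range(n)]
    bc = np.zeros(n)
    for s in range(n):
        dist = np.full(n, np.inf)
        sigma = np.zeros(n)
        dist[s] = 0.0
        sigma[s] = 1.0
        preds: list[list[int]] = [[] for _ in range(n)]
        order: list[int] = []
        done = np.zeros(n, dtype=bool)
        heap: list[tuple[float, int]] = [(0.0, s)]
        while heap:
            dv, v = heapq.heappop(heap)
            if done[v]:
                continue
            done[v] = True
            order.append(v)
            for u, l in zip(nbrs[v], lens[v]):
                if done[u]:
                    continue
                alt = dv + l
                if np.isinf(dist[u]):
                    dist[u] = alt
                    sigma[u] = sigma[v]
                    preds[u] = [v]
                    heapq.heappush(heap, (alt, u))
                    continue
                tol = _TIE_TOL * max(1.0, abs(dist[u]))
                if alt < dist[u] - tol:
                    dist[u] = alt
                    sigma[u] = sigma[v]
                    preds[u] = [v]
                    heapq.heappush(heap, (alt, u))
                elif abs(alt - dist[u]) <= tol:
                    sigma[u] += sigma[v]
                    preds[u].append(v)
        delta = np.zeros(n)
        for v in reversed(order):
            for p in preds[v]:
                delta[p] += sigma[p] / sigma[v] * (1.0 + delta[v])
            if v != s:
                bc[v] += delta[v]
    return bc / 2.0  # each unordered pair was visited from both endpoints


# ---------------------------------------------------------------------------
# Null networks and small-worldness

@dataclass
class NullEnsemble:
    """Cp and Lp of degree/weight-preserving random rewirings of one graph."""

    n_null: int
    cp: np.ndarray
    lp: np.ndarray

    @property
    def mean_cp(self) -> float:
        return float(self.cp.mean())

    @property
    def mean_lp(self) -> float:
        return float(self.lp.mean())


def rewire_preserving_degrees(
    m: ConnectivityMatrix,
    rng: np.random.Generator,
    swaps_per_edge: int = 10,
    max_connectivity_retries: int = 20,
) -> ConnectivityMatrix:
    """One connected Maslov-Sneppen rewiring; edges carry their weights.

    Performs ``swaps_per_edge * n_edges`` accepted double-edge swaps,
    rejecting proposals that would create self-loops or duplicate edges.  If
    the result is disconnected the rewiring is resampled from the original
    (bounded retries) so Lp of every null is finite.
    """
    ii, jj = np.nonzero(np.triu(m.weights, k=1))
    base_edges = list(zip(ii.tolist(), jj.tolist()))
    weights = m.weights[ii, jj]
    n_edges = len(base_edges)
    if n_edges < 2:
        return ConnectivityMatrix(m.scan_id, m.weights.copy(), list(m.node_labels))
    target = swaps_per_edge * n_edges

    n = m.weights.shape[0]
    enc = n  # unordered pair {u,v}, u<v, encoded as u*enc+v

    for _ in range(max_connectivity_retries):
        eu = [e[0] for e in base_edges]
        ev = [e[1] for e in base_edges]
        edge_set = {u * enc + v for u, v in base_edges}
        accepted = 0
        attempts = 0
        max_attempts = 200 * target
        batch = 4096
        buf_idx = buf_flip = None
        pos = batch
        while accepted < target and attempts < max_attempts:
            if pos >= batch:
                buf_idx = rng.integers(0, n_edges, size=(batch, 2)).tolist()
                buf_flip = (rng.random(batch) < 0.5).tolist()
                pos = 0
            e1, e2 = buf_idx[pos]
            flip = buf_flip[pos]
            pos += 1
            attempts += 1
            if e1 == e2:
                continue
            a, b = eu[e1], ev[e1]
            c, d = (ev[e2], eu[e2]) if flip else (eu[e2], ev[e2])
            # propose (a, d) and (c, b)
            if a == d or c == b:
                continue
            n1 = a * enc + d if a < d else d * enc + a
            n2 = c * enc + b if c < b else b * enc + c
            if n1 in edge_set or n2 in edge_set:
                continue
            edge_set.remove(eu[e1] * enc + ev[e1])
            edge_set.remove(eu[e2] * enc + ev[e2])
            edge_set.add(n1)
            edge_set.add(n2)
            eu[e1], ev[e1] = (a, d) if a < d else (d, a)
            eu[e2], ev[e2] = (c, b) if c < b else (b, c)
            accepted += 1
        if accepted < target:
            raise RuntimeError(
                f"rewiring stalled after {attempts} attempts (pathological topology)"
            )
        w = np.zeros((n, n))
        for u, v, wt in zip(eu, ev, weights):
            w[u, v] = wt
            w[v, u] = wt
        null = ConnectivityMatrix(m.scan_id, w, list(m.node_labels))
        if is_fully_connected(null):
            return null
    raise RuntimeError(
        f"no connected rewiring found in {max_connectivity_retries} retries"
    )


def generate_null(
    m: ConnectivityMatrix,
    n_null: int = 1000,
    seed: int | np.random.Generator | None = None,
    swaps_per_edge: int = 10,
) -> NullEnsemble:
    """Cp and Lp over ``n_null`` independent degree-preserving rewirings."""
    if n_null < 1:
        raise ValueError("n_null must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    cps = np.empty(n_null)
    lps = np.empty(n_null)
    for k in range(n_null):
        null = rewire_preserving_degrees(m, rng, swaps_per_edge=swaps_per_edge)
        cps[k], _ = clustering_coefficients(null)
        lps[k] = characteristic_path_length(null)
    return NullEnsemble(n_null=n_null, cp=cps, lp=lps)


def small_worldness(
    m: ConnectivityMatrix,
    ensemble: NullEnsemble,
    d: np.ndarray | None = None,
) -> tuple[float, float, float]:
    """(gamma, lambda, sigma) relative to the null ensemble means."""
    cp, _ = clustering_coefficients(m)
    lp = characteristic_path_length(m, d)
    gamma = cp / ensemble.mean_cp
    lam = lp / ensemble.mean_lp
    return gamma, lam, gamma / lam


# ---------------------------------------------------------------------------
# Per-scan metric bundle and long-format table

@dataclass
class GraphMetrics:
    """Global and nodal metric values for one scan."""

    scan_id: str
    cp: float
    lp: float
    gamma: float
    lam: float
    sigma: float
    eg: float
    mean_degree: float
    ncp: np.ndarray
    ne: np.ndarray
    bc: np.ndarray
    dc: np.ndarray
    node_labels: list[str] = field(default_factory=list)


def compute_metrics(
    m: ConnectivityMatrix,
    n_null: int = 1000,
    seed: int | np.random.Generator | None = None,
    swaps_per_edge: int = 10,
) -> GraphMetrics:
    """All global and nodal metrics for one connected scan."""
    d = shortest_path_lengths(m)
    cp, ncp = clustering_coefficients(m)
    lp = characteristic_path_length(m, d)
    eg = global_efficiency(m, d)
    ne = nodal_efficiency(m, d)
    bc = betweenness_centrality(m)
    dc, mean_dc = degree_centrality(m)
    ens = generate_null(m, n_null=n_null, seed=seed, swaps_per_edge=swaps_per_edge)
    gamma, lam, sigma = small_worldness(m, ens, d)
    return GraphMetrics(
        scan_id=m.scan_id, cp=cp, lp=lp, gamma=gamma, lam=lam, sigma=sigma,
        eg=eg, mean_degree=mean_dc, ncp=ncp, ne=ne, bc=bc,
        dc=dc.astype(float), node_labels=list(m.node_labels),
    )


GLOBAL_METRICS = ["Cp", "Lp", "gamma", "lambda", "sigma", "Eg", "mean_degree"]
NODAL_METRICS = ["NCp", "Ne", "Bc", "Dc"]


def metrics_to_long(all_metrics: list[GraphMetrics]) -> pd.DataFrame:
    """Long-format table: scan_id, level, region, hemisphere, metric, value."""
    rows = []
    for gm in all_metrics:
        for name, val in zip(
            GLOBAL_METRICS,
            [gm.cp, gm.lp, gm.gamma, gm.lam, gm.sigma, gm.eg, gm.mean_degree],
        ):
            rows.append((gm.scan_id, "global", "NA", "NA", name, val))
        for name, arr in zip(NODAL_METRICS, [gm.ncp, gm.ne, gm.bc, gm.dc]):
            for i, lab in enumerate(gm.node_labels):
                region, _, hemi = lab.rpartition(".")
                rows.append((gm.scan_id, "nodal", region or lab, hemi, name, arr[i]))
    return pd.DataFrame(
        rows, columns=["scan_id", "level", "region", "hemisphere", "metric", "value"]
    )


def write_node_file(
    values: np.ndarray,
    coordinates: np.ndarray,
    path,
    labels: list[str] | None = None,
    color: np.ndarray | None = None,
) -> None:
    """Write nodal values as a BrainNet-style .node file.

    Columns: x, y, z, color, size, label (whitespace-delimited).  Atlas
    centroid coordinates (90 x 3) are supplied by the caller; ``values``
    map to node size and ``color`` (defaults to the sign of the value).
    """
    values = np.asarray(values, dtype=float)
    coordinates = np.asarray(coordinates, dtype=float)
    if coordinates.shape != (len(values), 3):
        raise ValueError("coordinates must be (n_nodes, 3)")
    if color is None:
        color = np.sign(values)
    labels = labels or [f"n{i + 1}" for i in range(len(values))]
    with open(path, "w") as fh:
        for (x, y, z), c, v, lab in zip(coordinates, color, values, labels):
            fh.write(f"{x:.3f}\t{y:.3f}\t{z:.3f}\t{c:g}\t{v:g}\t{lab}\n")
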