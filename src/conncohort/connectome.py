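"""FA-weighted connectivity-matrix construction, validation and filtering.

Edges are the average fractional anisotropy (FA) of the fibres assigned to
each unordered region pair of a 90-node parcellation.  Matrices that are not
fully connected (single component spanning all nodes, edges = strictly
positive weights) are excluded from analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .parcellation import N_NODES, NODE_LABELS, hemisphere_of_index


@dataclass(frozen=True)
class FibreAssignment:
    """One tractography fibre assigned to an unordered node pair.

    Node indices are 1-based, as in the on-disk fibre tables.
    """

    fibre_id: int
    node_i: int
    node_j: int
    mean_fa: float


@dataclass
class ConnectivityMatrix:
    """Symmetric FA-weighted adjacency for one scan (zero diagonal)."""

    scan_id: str
    weights: np.ndarray
    node_labels: Sequence[str] = field(default_factory=lambda: list(NODE_LABELS))

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise ValueError("weights must be a square matrix")
        if len(self.node_labels) != w.shape[0]:
            raise ValueError("label count must equal matrix size")
        if not np.allclose(w, w.T, atol=1e-12):
            raise ValueError(f"matrix for {self.scan_id!r} is not symmetric")
        if np.any(np.diag(w) != 0):
            raise ValueError("diagonal must be zero (no self-loops)")
        if np.any(w < 0) or np.any(w > 1):
            raise ValueError("FA weights must lie in [0, 1]")
        self.weights = w

    @property
    def n_nodes(self) -> int:
        return self.weights.shape[0]

    def hemisphere(self, i: int) -> str:
        return hemisphere_of_index(i) if self.n_nodes == N_NODES else "NA"


def assemble_matrix(
    fibres: Iterable[FibreAssignment], n_nodes: int = N_NODES, scan_id: str = ""
) -> ConnectivityMatrix:
    """Average per-pair fibre FA into a symmetric adjacency matrix.

    weight(i, j) is the arithmetic mean of ``mean_fa`` over all fibres on the
    unordered pair {i, j}; pairs with no fibres get weight 0.  Self-loops and
    out-of-range indices or FA values are rejected.
    """
    total = np.zeros((n_nodes, n_nodes))
    count = np.zeros((n_nodes, n_nodes), dtype=int)
    for f in fibres:
        if not (1 <= f.node_i <= n_nodes and 1 <= f.node_j <= n_nodes):
            raise ValueError(
                f"fibre {f.fibre_id}: node index outside 1..{n_nodes}"
            )
        if f.node_i == f.node_j:
            raise ValueError(f"fibre {f.fibre_id}: self-loop {f.node_i}")
        if not 0.0 <= f.mean_fa <= 1.0:
            raise ValueError(f"fibre {f.fibre_id}: FA {f.mean_fa} outside [0, 1]")
        i, j = f.node_i - 1, f.node_j - 1
        total[i, j] += f.mean_fa
        total[j, i] += f.mean_fa
        count[i, j] += 1
        count[j, i] += 1
    with np.errstate(invalid="ignore"):
        w = np.where(count > 0, total / np.maximum(count, 1), 0.0)
    labels = list(NODE_LABELS) if n_nodes == N_NODES else [str(k + 1) for k in range(n_nodes)]
    return ConnectivityMatrix(scan_id=scan_id, weights=w, node_labels=labels)


def is_fully_connected(m: ConnectivityMatrix) -> bool:
    """True iff strictly-positive edges form one component over all nodes."""
    w = m.weights
    n = w.shape[0]
    seen = np.zeros(n, dtype=bool)
    stack = [0]
    seen[0] = True
    while stack:
        u = stack.pop()
        nbrs = np.nonzero((w[u] > 0) & ~seen)[0]
        seen[nbrs] = True
        stack.extend(nbrs.tolist())
    return bool(seen.all())


def filter_scans(
    matrices: Iterable[ConnectivityMatrix],
) -> tuple[list[ConnectivityMatrix], list[tuple[str, str]]]:
    """Partition scans into (kept, excluded-with-reason) by connectedness."""
    kept: list[ConnectivityMatrix] = []
    excluded: list[tuple[str, str]] = []
    for m in matrices:
        if is_fully_connected(m):
            kept.append(m)
        else:
            excluded.append((m.scan_id, "matrix not fully connected"))
    return kept, excluded


# ---------------------------------------------------------------------------
# I/O

def read_fibre_table(path: str | Path) -> list[FibreAssignment]:
    """Read a fibre assignment CSV (fibre_id,node_i,node_j,mean_fa)."""
    df = pd.read_csv(path)
    required = {"fibre_id", "node_i", "node_j", "mean_fa"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"fibre table {path} missing columns {sorted(missing)}")
    return [
        FibreAssignment(int(r.fibre_id), int(r.node_i), int(r.node_j), float(r.mean_fa))
        for r in df.itertuples()
    ]


def read_matrix(path: str | Path, scan_id: str | None = None) -> ConnectivityMatrix:
    """Read a whitespace-delimited square matrix text file."""
    w = np.loadtxt(path)
    sid = scan_id if scan_id is not None else Path(path).stem
    labels = list(NODE_LABELS) if w.shape[0] == N_NODES else [str(k + 1) for k in range(w.shape[0])]
    return ConnectivityMatrix(scan_id=sid, weights=w, node_labels=labels)


def write_matrix(m: ConnectivityMatrix, path: str | Path) -> None:
    np.savetxt(path, m.weights, fmt="%.8f")


def to_graphml(m: ConnectivityMatrix, path: str | Path) -> None:
    """Export the weighted graph as GraphML (nodes keep their region labels)."""
    import networkx as nx

    g = nx.Graph()
    for i, lab in enumerate(m.node_labels):
        g.add_node(lab, hemisphere=m.hemisphere(i))
    ii, jj = np.nonzero(np.triu(m.weights, k=1))
    for i, j in zip(ii.tolist(), jj.tolist()):
        g.add_edge(m.node_labels[i], m.node_labels[j], weight=float(m.weights[i, j]))
    nx.write_graphml(g, path)
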