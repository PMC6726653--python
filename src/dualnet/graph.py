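"""Topology statistics of the strong synaptic subnetwork.

All metrics are computed on the binarized, symmetrized adjacency: an
undirected edge exists between i and j when a synapse runs in either
direction.  The clustering coefficient averages 2*C_i / (k_i*(k_i-1)) over
all nodes (0 for k_i < 2); the characteristic path length averages BFS
distances over reachable ordered pairs, with unreachable pairs excluded and
counted.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.sparse.csgraph import dijkstra

from .network import NetworkConfig, SynapseTable, build_strong_network

__all__ = [
    "GraphMetrics",
    "binarize_and_symmetrize",
    "adjacency_from_edges",
    "clustering",
    "path_length",
    "beta_sweep_metrics",
]


@dataclass
class GraphMetrics:
    """Summary topology of one undirected graph."""

    CC: float                 # average clustering coefficient
    PL: float                 # mean shortest-path length (NaN if no pairs)
    C_i: np.ndarray           # triangles through each node
    D_i: np.ndarray           # degree of each node
    n_nodes: int
    n_edges: int              # undirected edge count
    excluded_pairs: int       # ordered pairs unreachable, excluded from PL


def adjacency_from_edges(pre: np.ndarray, post: np.ndarray,
                         n_nodes: int) -> sp.csr_matrix:
    """Binarized symmetrized adjacency from directed edges (diagonal zero)."""
    data = np.ones(len(pre), dtype=np.int8)
    a = sp.coo_matrix((data, (pre, post)), shape=(n_nodes, n_nodes)).tocsr()
    a = a.maximum(a.T)
    a.setdiag(0)
    a.eliminate_zeros()
    a.data = np.ones_like(a.data)
    return a

def binarize_and_symmetrize(table: SynapseTable,
                            class_filter: tuple[str, ...] = ("strong_EE",)
                            ) -> sp.csr_matrix:
    """Undirected adjacency of the synapses in the selected classes.

    E->E class filters yield an N_E x N_E matrix; any filter touching
    inhibitory neurons yields the full (N_E + N_I) square matrix.  An empty
    selection gives an all-zero adjacency.
    """
    mask = table.class_mask(*class_filter)
    ee_only = all(c in ("strong_EE", "weak_EE") for c in class_filter)
    n = table.n_E if ee_only else table.n_neurons
    return adjacency_from_edges(table.pre[mask], table.post[mask], n)


def clustering(adjacency: sp.spmatrix) -> tuple[float, np.ndarray]:
    """Average clustering coefficient and per-node triangle counts.

    C_i is the number of triangles through node i, computed as
    diag(A^3) / 2; the per-node coefficient 2*C_i / (k_i*(k_i-1)) is taken
    as 0 for nodes of degree < 2 and CC is its mean over all nodes.
    """
    a = sp.csr_matrix(adjacency, dtype=np.int64)
    k = np.asarray(a.sum(axis=1)).ravel()
    # diag(A^3)_i = sum_j (A^2)_ij * A_ij
    a2 = a @ a
    tri2 = np.asarray(a2.multiply(a).sum(axis=1)).ravel()
    c_i = tri2 // 2
    denom = k * (k - 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        local = np.where(denom > 0, 2.0 * c_i / np.maximum(denom, 1), 0.0)
    return float(local.mean()) if local.size else float("nan"), c_i


def path_length(adjacency: sp.spmatrix,
                chunk: int = 512) -> tuple[float, int, int]:
    """Characteristic path length by BFS from every node.

    Returns ``(PL, reachable_pairs, excluded_pairs)`` where PL is the mean
    of d_ij over ordered reachable pairs i != j.  A graph with no connected
    pair returns ``(nan, 0, n*(n-1))``.
    """
    a = sp.csr_matrix(adjacency)
    n = a.shape[0]
    total = 0.0
    reachable = 0
    for start in range(0, n, chunk):
        idx = np.arange(start, min(start + chunk, n))
        d = dijkstra(a, unweighted=True, indices=idx)
        d[np.arange(idx.size), idx] = np.inf  # drop i == j
        finite = np.isfinite(d)
        total += d[finite].sum()
        reachable += int(finite.sum())
    excluded = n * (n - 1) - reachable
    pl = total / reachable if reachable else float("nan")
    return pl, reachable, excluded


def metrics(adjacency: sp.spmatrix) -> GraphMetrics:
    """All topology statistics of one adjacency."""
    cc, c_i = clustering(adjacency)
    pl, _, excluded = path_length(adjacency)
    k = np.asarray(sp.csr_matrix(adjacency).sum(axis=1)).ravel()
    return GraphMetrics(
        CC=cc, PL=pl, C_i=c_i, D_i=k.astype(np.int64),
        n_nodes=adjacency.shape[0],
        n_edges=int(k.sum()) // 2,
        excluded_pairs=excluded,
    )


def beta_sweep_metrics(config: NetworkConfig, betas: list[float],
                       seed: int | None = None,
                       compute_pl: bool = True
                       ) -> tuple[pd.DataFrame, dict[float, GraphMetrics]]:
    """CC and PL of the strong network across rewiring probabilities.

    The beta = 0 baseline is built from the same seed, so the EPSP draw (and
    hence the strong-edge count) is held fixed and only the rewiring varies.
    Ratios CC(beta)/CC(0) and PL(beta)/PL(0) are NaN-flagged when the
    baseline is zero.
    """
    seed = config.seed if seed is None else seed
    per_beta: dict[float, GraphMetrics] = {}
    for b in dict.fromkeys([0.0, *betas]):
        pre, post, _ = build_strong_network(config, beta=b, seed=seed)
        adj = adjacency_from_edges(pre, post, config.N_E)
        cc, c_i = clustering(adj)
        if compute_pl:
            pl, _, excluded = path_length(adj)
        else:
            pl, excluded = float("nan"), 0
        k = np.asarray(adj.sum(axis=1)).ravel().astype(np.int64)
        per_beta[b] = GraphMetrics(cc, pl, c_i, k, config.N_E,
                                   int(k.sum()) // 2, excluded)
    base = per_beta[0.0]
    rows = []
    for b in betas:
        g = per_beta[b]
        rows.append({
            "beta": b,
            "CC": g.CC,
            "CC_ratio": g.CC / base.CC if base.CC else float("nan"),
            "PL": g.PL,
            "PL_ratio": g.PL / base.PL if base.PL else float("nan"),
            "excluded_pairs": g.excluded_pairs,
        })
    return pd.DataFrame(rows), per_beta
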