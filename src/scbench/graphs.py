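"""Graph construction from expression matrices and weighted propagation.

The central object here is the weighted bipartite cell-gene graph: cell and
gene nodes, an edge wherever a cell expresses a gene, with weight equal to
that gene's fraction of the cell's total counts, so the weights incident to
each cell sum to one.  No edge ever joins two cells or two genes.  A kNN
cell-cell graph and the usual symmetric / row adjacency normalizations and
the linear propagation step used by all the graph models live here too.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

from .data import SCDataset, ValidationError


@dataclass
class Graph:
    """Undirected weighted graph with typed nodes (cell / gene / spot).

    Nodes are (id, role) pairs; edges are stored once per unordered pair in a
    symmetric sparse adjacency.  ``bipartite`` graphs never join two nodes of
    the same role.
    """

    node_ids: list
    node_roles: list
    adj: sp.csr_matrix
    bipartite: bool = False
    normalized: str = None  # None | "sym" | "row"

    def __post_init__(self):
        A = self.adj
        if A.shape[0] != A.shape[1] or A.shape[0] != len(self.node_ids):
            raise ValidationError("adjacency shape does not match node list")
        if len(self.node_roles) != len(self.node_ids):
            raise ValidationError("roles must match nodes")
        if A.nnz:
            d = A.data
            if not np.all(np.isfinite(d)) or d.min() < 0:
                raise ValidationError("edge weights must be finite and >= 0")
        if self.normalized is None and (A != A.T).nnz != 0:
            raise ValidationError("adjacency must be symmetric")
        if self.bipartite:
            roles = np.asarray(self.node_roles)
            coo = A.tocoo()
            off = coo.row != coo.col
            if np.any(roles[coo.row[off]] == roles[coo.col[off]]):
                raise ValidationError("bipartite graph has an edge within one role")

    @property
    def n_nodes(self):
        return len(self.node_ids)

    def degrees(self) -> np.ndarray:
        return np.asarray(self.adj.sum(axis=1)).ravel()

    def edges(self):
        """Iterate (u, v, w) once per unordered pair, u <= v."""
        coo = sp.triu(self.adj).tocoo()
        return list(zip(coo.row.tolist(), coo.col.tolist(), coo.data.tolist()))


def cell_gene_graph(ds: SCDataset) -> Graph:
    """Weighted bipartite cell-gene graph from raw counts.

    Edge (cell c, gene g) exists iff the raw count X[c, g] > 0, with weight
    X[c, g] / (total counts of cell c): each cell's incident weights sum to 1.
    Cell nodes come first in the node order, then gene nodes.
    """
    X = sp.csr_matrix(ds.raw())
    totals = np.asarray(X.sum(axis=1)).ravel()
    if np.any(totals == 0):
        raise ValidationError("all-zero cell present; filter cells first")
    W = sp.diags(1.0 / totals) @ X  # cells x genes, rows sum to 1
    n, g = ds.shape
    A = sp.bmat([[sp.csr_matrix((n, n)), W], [W.T, sp.csr_matrix((g, g))]], format="csr")
    return Graph(node_ids=list(ds.cell_ids) + list(ds.gene_ids),
                 node_roles=["cell"] * n + ["gene"] * g,
                 adj=A, bipartite=True)


def knn_graph(embedding: np.ndarray, k: int, metric: str = "euclidean") -> Graph:
    """Mutualized-union kNN cell-cell graph with unit weights.

    Edge (i, j) is present iff j is among i's k nearest neighbours or vice
    versa.  Distance ties are broken by ascending index, so the graph is
    deterministic for duplicated points.
    """
    Z = np.asarray(embedding, dtype=np.float64)
    n = Z.shape[0]
    if not 1 <= k < n:
        raise ValueError(f"k must be in [1, {n - 1}]")
    if metric == "euclidean":
        sq = (Z ** 2).sum(axis=1)
        D = sq[:, None] + sq[None, :] - 2 * Z @ Z.T
    elif metric == "cosine":
        norms = np.linalg.norm(Z, axis=1)
        norms[norms == 0] = 1.0
        D = 1 - (Z @ Z.T) / np.outer(norms, norms)
    else:
        raise ValueError("metric must be 'euclidean' or 'cosine'")
    np.fill_diagonal(D, np.inf)
    rows, cols = [], []
    for i in range(n):
        order = np.lexsort((np.arange(n), D[i]))  # distance, then index
        for j in order[:k]:
            rows.append(i)
            cols.append(int(j))
    A = sp.csr_matrix((np.ones(len(rows)), (rows, cols)), shape=(n, n))
    A = A.maximum(A.T)  # union of neighbourhoods, unit weights
    return Graph(node_ids=[f"cell{i}" for i in range(n)],
                 node_roles=["cell"] * n, adj=A, bipartite=False)


def normalize_adjacency(g: Graph, mode: str = "sym", add_self_loops: bool = True) -> Graph:
    """Symmetric (D^-1/2 A D^-1/2) or row (D^-1 A) normalization."""
    A = g.adj.copy().tolil()
    if add_self_loops:
        A.setdiag(np.asarray(A.diagonal()) + 1.0)
    A = A.tocsr()
    d = np.asarray(A.sum(axis=1)).ravel()
    if mode == "sym":
        with np.errstate(divide="ignore"):
            dinv = np.where(d > 0, 1.0 / np.sqrt(np.where(d > 0, d, 1.0)), 0.0)
        An = sp.diags(dinv) @ A @ sp.diags(dinv)
    elif mode == "row":
        if np.any(d == 0):
            raise ValidationError(
                "row normalization undefined for isolated nodes; add self loops")
        An = sp.diags(1.0 / d) @ A
    else:
        raise ValueError("mode must be 'sym' or 'row'")
    return Graph(node_ids=list(g.node_ids), node_roles=list(g.node_roles),
                 adj=An.tocsr(), bipartite=g.bipartite, normalized=mode)


def propagate(features: np.ndarray, g: Graph) -> np.ndarray:
    """One message-passing step: out[v] = sum_u w(u, v) features[u].

    The graph is expected to be normalized already; propagation is linear in
    the features.
    """
    F = np.asarray(features, dtype=np.float64)
    if F.shape[0] != g.n_nodes:
        raise ValueError(f"features have {F.shape[0]} rows for {g.n_nodes} nodes")
    return g.adj @ F
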