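"""KNN/SNN graph construction and Louvain community detection.

Cells are linked to their k exact nearest neighbors in the PCA embedding
(Euclidean distance, ties broken toward the lower cell index), a shared
nearest-neighbor (SNN) graph re-weights pairs by the Jaccard overlap of
their neighbor sets (each set includes the cell itself), weak edges are
pruned, and weighted-modularity Louvain partitions the result. The same
routines serve every round of the iterative engine, so k is automatically
capped for small subsets.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import networkx as nx
import scipy.sparse
from networkx.algorithms.community import louvain_communities, modularity
from scipy.spatial.distance import cdist

from .preprocess import EmbeddingMatrix


class ClusteringError(ValueError):
    pass


@dataclass
class NeighborGraph:
    """Per-cell ordered nearest-neighbor indices (self excluded)."""

    indices: np.ndarray  # (n_cells, k_eff), int
    k: int  # requested k (effective k is indices.shape[1])

    @property
    def n_cells(self) -> int:
        return self.indices.shape[0]

    @property
    def k_effective(self) -> int:
        return self.indices.shape[1]


@dataclass
class SNNGraph:
    """Undirected Jaccard-weighted graph over cells, weak edges pruned."""

    weights: scipy.sparse.csr_matrix  # symmetric, zero diagonal
    prune: float

    @property
    def n_cells(self) -> int:
        return self.weights.shape[0]


@dataclass
class ClusterLabeling:
    """0-based contiguous cluster ids for one Louvain round."""

    labels: np.ndarray
    resolution: float
    seed: int
    modularity: float

    @property
    def n_clusters(self) -> int:
        return int(self.labels.max()) + 1 if self.labels.size else 0

    def members(self, cluster: int) -> np.ndarray:
        return np.flatnonzero(self.labels == cluster)


def knn_graph(embedding: EmbeddingMatrix | np.ndarray, k: int = 20) -> NeighborGraph:
    """Exact k nearest neighbors; k is capped at n_cells - 1."""
    X = embedding.scores if isinstance(embedding, EmbeddingMatrix) else np.asarray(embedding)
    n = X.shape[0]
    if n < 2:
        raise ClusteringError("nearest-neighbor graph needs at least 2 cells")
    if k < 1:
        raise ClusteringError("k must be >= 1")
    k_eff = min(k, n - 1)
    dist = cdist(X, X)
    np.fill_diagonal(dist, np.inf)
    # stable sort on distance keeps the lower index first among ties
    order = np.argsort(dist, axis=1, kind="stable")
    return NeighborGraph(indices=order[:, :k_eff].astype(np.int64), k=k)


def snn_graph(knn: NeighborGraph, prune: float = 1.0 / 15.0) -> SNNGraph:
    """Jaccard overlap of neighbor sets (including self); drop weights < prune."""
    n, k_eff = knn.indices.shape
    rows = np.repeat(np.arange(n), k_eff + 1)
    cols = np.concatenate([knn.indices, np.arange(n)[:, None]], axis=1).ravel()
    data = np.ones(rows.size)
    A = scipy.sparse.csr_matrix((data, (rows, cols)), shape=(n, n))
    inter = (A @ A.T).tocoo()
    set_size = k_eff + 1
    union = 2 * set_size - inter.data
    weights = inter.data / union
    keep = (weights >= prune) & (inter.row != inter.col)
    W = scipy.sparse.csr_matrix(
        (weights[keep], (inter.row[keep], inter.col[keep])), shape=(n, n)
    )
    return SNNGraph(weights=W, prune=prune)


def _as_nx(graph: SNNGraph | scipy.sparse.spmatrix | np.ndarray) -> nx.Graph:
    """Canonical graph build: nodes 0..n-1 in order, edges sorted by (i, j)."""
    W = graph.weights if isinstance(graph, SNNGraph) else scipy.sparse.csr_matrix(graph)
    n = W.shape[0]
    G = nx.Graph()
    G.add_nodes_from(range(n))
    coo = W.tocoo()
    edges = sorted(
        (int(i), int(j), float(v))
        for i, j, v in zip(coo.row, coo.col, coo.data)
        if i < j and v != 0
    )
    G.add_weighted_edges_from(edges)
    return G


def _refine_by_local_moves(G: nx.Graph, comms: list, resolution: float) -> tuple[list, float]:
    """Hill-climb to local optimality: greedy single-node moves (including
    splitting off a singleton) and pairwise community merges until neither
    improves modularity. Cheap for small graphs; polishes the local optima
    the multi-level sweep can settle into."""
    comms = [set(c) for c in comms]
    best = modularity(G, comms, weight="weight", resolution=resolution)
    improved = True
    while improved:
        improved = False
        for node in G.nodes:
            src = next(i for i, c in enumerate(comms) if node in c)
            targets = list(range(len(comms))) + [None]  # None: new singleton
            for dst in targets:
                if dst == src:
                    continue
                trial = [set(c) for c in comms]
                trial[src].discard(node)
                if dst is None:
                    trial.append({node})
                else:
                    trial[dst].add(node)
                trial = [c for c in trial if c]
                mod = modularity(G, trial, weight="weight", resolution=resolution)
                if mod > best + 1e-12:
                    comms, best, improved = trial, mod, True
                    break
        if not improved:
            for i, j in itertools.combinations(range(len(comms)), 2):
                trial = [set(c) for k, c in enumerate(comms) if k not in (i, j)]
                trial.append(comms[i] | comms[j])
                mod = modularity(G, trial, weight="weight", resolution=resolution)
                if mod > best + 1e-12:
                    comms, best, improved = trial, mod, True
                    break
    return comms, best


def louvain(
    graph: SNNGraph | scipy.sparse.spmatrix | np.ndarray,
    resolution: float = 1.0,
    seed: int = 42,
    n_restarts: int = 5,
) -> ClusterLabeling:
    """Weighted-modularity Louvain with seeded restarts.

    Louvain is a greedy heuristic, so ``n_restarts`` sweeps are run from
    seeds ``seed .. seed + n_restarts - 1`` and the partition with the
    highest modularity is kept (the earliest restart wins ties), making the
    result deterministic for a given (graph, resolution, seed). Cluster ids
    are renumbered contiguously from 0 in order of each cluster's smallest
    member index.
    """
    G = _as_nx(graph)
    n = G.number_of_nodes()
    if n == 0:
        raise ClusteringError("cannot cluster an empty graph")
    if G.number_of_edges() == 0:
        labels = np.arange(n)
        return ClusterLabeling(labels, resolution, seed, 0.0)
    # restarts and refinement trade quality for time: tiny graphs have deep
    # greedy basins and cost nothing to polish (extra hill-climbs are run
    # from seeded random partitions); large graphs are stable under a few
    # multi-level sweeps and local refinement would dominate runtime
    refine = n <= 12
    restart_plan = max(1, n_restarts) + (40 if refine else 0)
    rng = np.random.default_rng(seed)
    best_comms, best_mod = None, -np.inf
    for i in range(restart_plan):
        if i < max(1, n_restarts):
            comms = louvain_communities(
                G, weight="weight", resolution=resolution, seed=seed + i
            )
        else:
            n_parts = int(rng.integers(1, n + 1))
            member = rng.integers(0, n_parts, size=n)
            comms = [set(np.flatnonzero(member == c)) for c in range(n_parts)]
            comms = [c for c in comms if c]
        mod = modularity(G, comms, weight="weight", resolution=resolution)
        if refine:
            comms, mod = _refine_by_local_moves(G, comms, resolution)
        if mod > best_mod + 1e-12:
            best_comms, best_mod = comms, mod
    labels = np.empty(n, dtype=np.int64)
    ordered = sorted(best_comms, key=min)
    for cid, community in enumerate(ordered):
        for node in community:
            labels[node] = cid
    return ClusterLabeling(labels, resolution, seed, float(best_mod))
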