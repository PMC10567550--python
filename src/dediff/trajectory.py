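"""Pseudotime on a principal graph, directed pseudotime-kernel transition
matrix, smoothed gene trends and trend-module detection.

The principal graph is a minimum spanning tree over k-means centroids in PC
space (a simplified Monocle-style backbone). Pseudotime is the geodesic
distance from a root node plus a within-node projection, min-max scaled to
[0, 1]. The transition matrix follows the pseudotime-kernel idea: KNN
similarities are damped exponentially for edges that move backward in
pseudotime, then row-normalized into a Markov transition matrix.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import networkx as nx
from scipy import sparse
from scipy.sparse.csgraph import minimum_spanning_tree
from sklearn.cluster import KMeans

from .sc_core import EmbeddingResult, NormalizedMatrix, knn_graph

__all__ = [
    "PrincipalGraph",
    "PseudotimeVector",
    "TransitionMatrix",
    "GeneTrendSet",
    "ModuleSet",
    "fit_principal_graph",
    "compute_pseudotime",
    "pseudotime_kernel",
    "gene_trends",
    "detect_modules",
]


@dataclass
class PrincipalGraph:
    node_positions: np.ndarray  # n_nodes x n_pcs
    edges: list[tuple[int, int]]  # MST edges, weights implicit (Euclidean)
    assignments: np.ndarray  # cell -> node

    @property
    def n_nodes(self) -> int:
        return self.node_positions.shape[0]

    def as_networkx(self) -> nx.Graph:
        G = nx.Graph()
        G.add_nodes_from(range(self.n_nodes))
        for u, v in self.edges:
            w = float(np.linalg.norm(self.node_positions[u] - self.node_positions[v]))
            G.add_edge(u, v, weight=w)
        return G


@dataclass
class PseudotimeVector:
    t: np.ndarray  # per cell, in [0, 1]
    root_node: int


@dataclass
class TransitionMatrix:
    matrix: sparse.csr_matrix  # row-stochastic
    k_neighbors: int
    sigma: float


@dataclass
class GeneTrendSet:
    grid: np.ndarray  # strictly increasing pseudotime grid
    trends: np.ndarray  # genes x grid
    gene_ids: list[str]
    span: float


@dataclass
class ModuleSet:
    labels: np.ndarray  # module per gene, contiguous from 0
    gene_ids: list[str]
    resolution: float

    @property
    def n_modules(self) -> int:
        return int(self.labels.max()) + 1 if self.labels.size else 0

    def members(self, module: int) -> list[str]:
        return [g for g, m in zip(self.gene_ids, self.labels) if m == module]


def fit_principal_graph(
    embedding: EmbeddingResult, n_nodes: int = 20, seed: int = 0
) -> PrincipalGraph:
    """K-means centroids joined by a Euclidean minimum spanning tree."""
    coords = embedding.coordinates
    if n_nodes < 2:
        raise ValueError("n_nodes must be >= 2")
    if n_nodes > coords.shape[0]:
        raise ValueError("n_nodes cannot exceed n_cells")
    km = KMeans(n_clusters=n_nodes, n_init=10, random_state=seed)
    assignments = km.fit_predict(coords)
    centers = km.cluster_centers_
    d = np.linalg.norm(centers[:, None, :] - centers[None, :, :], axis=2)
    mst = minimum_spanning_tree(d).tocoo()
    edges = [(int(u), int(v)) for u, v in zip(mst.row, mst.col)]
    return PrincipalGraph(node_positions=centers, edges=edges, assignments=assignments)


def compute_pseudotime(
    graph: PrincipalGraph,
    cells: np.ndarray,
    root_node: int | None = None,
    root_scores: np.ndarray | None = None,
    smooth_graph: sparse.spmatrix | None = None,
    smooth_iterations: int = 2,
) -> PseudotimeVector:
    """Geodesic distance from the root node along the principal tree, with
    each cell projected onto its nearest tree edge, clipped at zero and
    min-max scaled to [0, 1].

    The root is given explicitly or resolved as the node whose assigned cells
    maximize the mean of ``root_scores`` (e.g. a differentiated-signature
    score per cell). When a KNN similarity graph is supplied, the raw
    pseudotime is relaxed over it (t <- (t + P t)/2, ``smooth_iterations``
    times) to suppress local projection noise before rescaling.
    """
    G = graph.as_networkx()
    if not nx.is_connected(G):
        raise ValueError("principal graph is disconnected")
    if root_node is None:
        if root_scores is None:
            raise ValueError("provide root_node or root_scores")
        means = np.full(graph.n_nodes, -np.inf)
        for v in range(graph.n_nodes):
            m = graph.assignments == v
            if m.any():
                means[v] = float(np.mean(root_scores[m]))
        root_node = int(np.argmax(means))
    dist = nx.single_source_dijkstra_path_length(G, root_node, weight="weight")
    node_dist = np.array([dist[v] for v in range(graph.n_nodes)])

    # project every cell onto its nearest tree edge; pseudotime interpolates
    # the geodesic node distances along that edge
    pos = graph.node_positions
    best_d2 = np.full(cells.shape[0], np.inf)
    raw = np.zeros(cells.shape[0])
    for u, v in graph.edges:
        a, b = pos[u], pos[v]
        ab = b - a
        denom = float(ab @ ab)
        s = ((cells - a) @ ab) / denom if denom > 0 else np.zeros(cells.shape[0])
        s = np.clip(s, 0.0, 1.0)
        proj = a + s[:, None] * ab
        d2 = np.sum((cells - proj) ** 2, axis=1)
        better = d2 < best_d2
        best_d2[better] = d2[better]
        raw[better] = node_dist[u] + s[better] * (node_dist[v] - node_dist[u])
    raw = np.clip(raw, 0.0, None)
    if smooth_graph is not None and smooth_iterations > 0:
        W = sparse.csr_matrix(smooth_graph)
        rowsum = np.asarray(W.sum(axis=1)).ravel()
        rowsum[rowsum == 0] = 1.0
        for _ in range(smooth_iterations):
            raw = 0.5 * raw + 0.5 * (W @ raw) / rowsum
    span = raw.max() - raw.min()
    t = (raw - raw.min()) / span if span > 0 else np.zeros_like(raw)
    return PseudotimeVector(t=t, root_node=root_node)


def pseudotime_kernel(
    similarities: sparse.spmatrix,
    pseudotime: PseudotimeVector,
    sigma: float | None = None,
    k_neighbors: int = 0,
    self_loops: bool = False,
) -> TransitionMatrix:
    """Row-stochastic directed transition matrix on a KNN similarity graph.

    Edge weight w_ij = s_ij * exp(-max(0, t_i - t_j) / sigma): moving to a
    neighbour earlier in pseudotime is damped softly, moving forward is not.
    Default sigma is the median over cells of the per-step neighbour
    pseudotime spacing (neighbour t spread divided by the number of
    neighbour intervals), i.e. the scale of a single Markov step.
    """
    S = sparse.csr_matrix(similarities)
    t = pseudotime.t
    n = S.shape[0]
    if sigma is None:
        spacings = []
        for i in range(n):
            nb = S.indices[S.indptr[i]:S.indptr[i + 1]]
            if nb.size:
                spread = float(t[nb].max() - t[nb].min())
                spacings.append(spread / max(nb.size - 1, 1))
        sigma = float(np.median(spacings)) if spacings else 0.0
        sigma = max(sigma, 1e-6)
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    C = S.tocoo()
    back = np.maximum(0.0, t[C.row] - t[C.col])
    w = C.data * np.exp(-back / sigma)
    W = sparse.csr_matrix((w, (C.row, C.col)), shape=S.shape)
    rowsum = np.asarray(W.sum(axis=1)).ravel()
    isolated = rowsum == 0
    if isolated.any():
        if not self_loops:
            raise ValueError(f"{int(isolated.sum())} isolated cells in the KNN graph")
        W = W + sparse.diags(isolated.astype(float))
        rowsum = np.asarray(W.sum(axis=1)).ravel()
    P = sparse.diags(1.0 / rowsum) @ W
    return TransitionMatrix(matrix=P.tocsr(), k_neighbors=k_neighbors, sigma=float(sigma))


def forward_mass_fraction(tm: TransitionMatrix, t: np.ndarray) -> float:
    """Fraction of interior cells whose forward transition mass (to strictly
    higher-t neighbours) is at least the backward mass. Interior cells are
    those with both earlier and later neighbours."""
    P = tm.matrix.tocoo()
    fwd = np.zeros(P.shape[0])
    bwd = np.zeros(P.shape[0])
    has_fwd = np.zeros(P.shape[0], dtype=bool)
    has_bwd = np.zeros(P.shape[0], dtype=bool)
    later = t[P.col] > t[P.row]
    earlier = t[P.col] < t[P.row]
    np.add.at(fwd, P.row[later], P.data[later])
    np.add.at(bwd, P.row[earlier], P.data[earlier])
    has_fwd[P.row[later]] = True
    has_bwd[P.row[earlier]] = True
    interior = has_fwd & has_bwd
    if not interior.any():
        return float("nan")
    return float(np.mean(fwd[interior] >= bwd[interior]))


def loess_smooth(
    t: np.ndarray, Y: np.ndarray, grid: np.ndarray, span: float
) -> np.ndarray:
    """Tricube-weighted local linear regression of each row of ``Y`` on ``t``,
    evaluated at ``grid`` (single pass, no robustness iterations).

    Vectorized over rows: at each grid point the fitted value is a linear
    functional of y, so all genes share one weight vector.
    """
    t = np.asarray(t, dtype=float)
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    n = t.size
    r = max(int(np.ceil(span * n)), 3)
    out = np.empty((Y.shape[0], grid.size))
    for k, x in enumerate(grid):
        d = np.abs(t - x)
        h = np.partition(d, r - 1)[r - 1]
        h = max(h, 1e-12)
        w = np.clip(1.0 - (d / h) ** 3, 0.0, None) ** 3
        dt = t - x
        s0 = w.sum()
        s1 = float(w @ dt)
        s2 = float(w @ (dt * dt))
        denom = s0 * s2 - s1 * s1
        if denom > 1e-14 * max(s0 * s2, 1e-300):
            a = w * (s2 - s1 * dt) / denom
        else:  # degenerate window (all points at one t): weighted mean
            a = w / s0
        out[:, k] = Y @ a
    return out


def gene_trends(
    norm: NormalizedMatrix,
    pseudotime: PseudotimeVector,
    genes: np.ndarray | None = None,
    span: float = 0.3,
    n_grid: int = 100,
) -> GeneTrendSet:
    """Local-linear (tricube-weighted) regression of each gene on pseudotime,
    evaluated on a fixed strictly increasing grid."""
    if not 0 < span <= 1:
        raise ValueError("span must lie in (0, 1]")
    t = pseudotime.t
    if t.shape[0] < 10:
        raise ValueError("need at least 10 cells for trend fitting")
    genes = np.arange(norm.n_genes) if genes is None else np.asarray(genes)
    lo, hi = float(t.min()), float(t.max())
    if hi <= lo:
        raise ValueError("degenerate pseudotime (all equal)")
    grid = np.linspace(lo, hi, n_grid)
    trends = loess_smooth(t, norm.values[genes], grid, span)
    if not np.all(np.isfinite(trends)):
        raise ValueError("trend fit failed for a gene")
    return GeneTrendSet(
        grid=grid,
        trends=trends,
        gene_ids=[norm.gene_ids[g] for g in genes],
        span=span,
    )


def detect_modules(
    trends: GeneTrendSet,
    k_neighbors: int = 10,
    resolution: float = 1.0,
    seed: int = 0,
) -> ModuleSet:
    """Communities of genes with similar standardized trends.

    Trends are z-scored along the grid, a gene-gene KNN graph is built on the
    standardized trend vectors, and Louvain modularity communities (seeded)
    give the modules, relabelled by decreasing size.
    """
    T = trends.trends
    if T.shape[0] < 2:
        raise ValueError("need at least 2 genes")
    sd = T.std(axis=1)
    if np.all(sd == 0):
        raise ValueError("all trends constant; z-scoring undefined")
    Z = (T - T.mean(axis=1, keepdims=True)) / np.where(sd > 0, sd, 1.0)[:, None]
    k = min(k_neighbors, T.shape[0] - 1)
    W = knn_graph(Z, k)
    G = nx.from_scipy_sparse_array(W)
    comms = nx.community.louvain_communities(G, resolution=resolution, seed=seed)
    comms = sorted(comms, key=lambda c: (-len(c), min(c)))
    labels = np.empty(T.shape[0], dtype=int)
    for lab, members in enumerate(comms):
        labels[list(members)] = lab
    return ModuleSet(labels=labels, gene_ids=list(trends.gene_ids), resolution=resolution)
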