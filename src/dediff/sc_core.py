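"""Single-cell workflow core: QC, normalization, batch correction, embedding,
clustering, signature scoring and differential expression.

The stages mirror a standard Smart-seq2 analysis: cells with too few detected
genes are dropped, counts are scaled by median-ratio size factors and
log-transformed, batch effects are removed with a parametric empirical-Bayes
location/scale adjustment (ComBat), highly variable genes feed a PCA embedding,
and groups of cells are compared with a tie-corrected Wilcoxon rank-sum test
with Benjamini-Hochberg adjustment.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import networkx as nx
from scipy import sparse, stats
from scipy.io import mmread
from sklearn.decomposition import PCA
from sklearn.neighbors import NearestNeighbors
from statsmodels.stats.multitest import multipletests

__all__ = [
    "CountMatrix",
    "CellAnnotations",
    "NormalizedMatrix",
    "EmbeddingResult",
    "ClusterAssignment",
    "DifferentialTable",
    "filter_cells",
    "normalize",
    "select_hvg",
    "batch_correct",
    "pca_embed",
    "cluster_cells",
    "signature_score",
    "compartment_correlation",
    "wilcoxon_de",
    "read_counts_mtx",
    "read_counts_csv",
    "read_cell_metadata",
]

LINEAGES = ("pos", "neg")
TIMEPOINTS = (0, 6, 9, 11)


@dataclass
class CountMatrix:
    """Raw integer counts, genes x cells."""

    values: np.ndarray
    gene_ids: list[str]
    cell_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        self.gene_ids = list(self.gene_ids)
        self.cell_ids = list(self.cell_ids)
        if self.values.ndim != 2:
            raise ValueError("counts must be 2-D (genes x cells)")
        if self.values.shape != (len(self.gene_ids), len(self.cell_ids)):
            raise ValueError("counts shape inconsistent with gene/cell ids")
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("duplicate gene ids")
        if len(set(self.cell_ids)) != len(self.cell_ids):
            raise ValueError("duplicate cell ids")
        if np.any(self.values < 0):
            raise ValueError("negative counts")

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_cells(self) -> int:
        return self.values.shape[1]


@dataclass
class CellAnnotations:
    """Per-cell labels: lineage in {pos, neg}, timepoint in {0, 6, 9, 11} days,
    batch id, and optionally the Itga6 sort gate."""

    table: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"cell_id", "lineage", "timepoint", "batch"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"metadata missing columns: {sorted(missing)}")
        if self.table["cell_id"].duplicated().any():
            raise ValueError("duplicate cell_id in metadata")
        bad_lin = set(self.table["lineage"]) - set(LINEAGES)
        if bad_lin:
            raise ValueError(f"unknown lineage labels: {sorted(bad_lin)}")
        bad_tp = set(int(t) for t in self.table["timepoint"]) - set(TIMEPOINTS)
        if bad_tp:
            raise ValueError(f"unknown timepoints: {sorted(bad_tp)}")
        self.table = self.table.reset_index(drop=True)

    def aligned_to(self, cell_ids: list[str]) -> pd.DataFrame:
        """Return one metadata row per requested cell, in order."""
        idx = self.table.set_index("cell_id")
        missing = [c for c in cell_ids if c not in idx.index]
        if missing:
            raise KeyError(f"cells absent from metadata: {missing[:5]}")
        return idx.loc[cell_ids].reset_index()


@dataclass
class NormalizedMatrix:
    """log1p size-factor-normalized expression, genes x cells."""

    values: np.ndarray
    gene_ids: list[str]
    cell_ids: list[str]
    size_factors: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.size_factors = np.asarray(self.size_factors, dtype=float)
        if np.any(self.size_factors <= 0):
            raise ValueError("size factors must be positive")
        if self.values.shape != (len(self.gene_ids), len(self.cell_ids)):
            raise ValueError("shape inconsistent with ids")

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_cells(self) -> int:
        return self.values.shape[1]

    def gene_index(self, gene: str) -> int:
        try:
            return self.gene_ids.index(gene)
        except ValueError:
            raise KeyError(f"gene {gene!r} not present") from None


@dataclass
class EmbeddingResult:
    coordinates: np.ndarray  # cells x n_pcs
    loadings: np.ndarray  # genes(hvg) x n_pcs
    explained_variance: np.ndarray
    n_pcs: int
    hvg: np.ndarray  # indices into the gene axis


@dataclass
class ClusterAssignment:
    labels: np.ndarray
    resolution: float
    k_neighbors: int

    @property
    def n_clusters(self) -> int:
        return int(self.labels.max()) + 1 if self.labels.size else 0


@dataclass
class DifferentialTable:
    """Per-gene Wilcoxon DE results between two cell groups."""

    table: pd.DataFrame = field(default_factory=pd.DataFrame)

    COLUMNS = ("gene", "lfc", "pct1", "pct2", "p", "p_adj")

    def to_tsv(self, path) -> None:
        self.table.loc[:, list(self.COLUMNS)].to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# IO
# ---------------------------------------------------------------------------

def read_counts_mtx(mtx_path, genes_path, barcodes_path) -> CountMatrix:
    """Read a genes x cells MTX triplet with TSV row/column sidecars."""
    mat = mmread(str(mtx_path))
    genes = pd.read_csv(genes_path, sep="\t", header=None)[0].tolist()
    cells = pd.read_csv(barcodes_path, sep="\t", header=None)[0].tolist()
    values = np.asarray(sparse.coo_matrix(mat).todense())
    return CountMatrix(values=np.rint(values).astype(np.int64), gene_ids=genes, cell_ids=cells)


def read_counts_csv(path) -> CountMatrix:
    """Dense CSV, genes as rows, header row holds cell ids."""
    df = pd.read_csv(path, index_col=0)
    return CountMatrix(
        values=df.to_numpy(dtype=np.int64),
        gene_ids=[str(g) for g in df.index],
        cell_ids=[str(c) for c in df.columns],
    )


def read_cell_metadata(path) -> CellAnnotations:
    return CellAnnotations(pd.read_csv(path, sep="\t"))


# ---------------------------------------------------------------------------
# QC and normalization
# ---------------------------------------------------------------------------

def filter_cells(counts: CountMatrix, min_genes: int = 200) -> CountMatrix:
    """Drop cells detecting fewer than ``min_genes`` genes (count > 0)."""
    if counts.n_cells == 0 or counts.n_genes == 0:
        raise ValueError("empty count matrix")
    detected = (counts.values > 0).sum(axis=0)
    keep = detected >= min_genes
    if not keep.any():
        raise ValueError("all cells removed by the detected-gene filter")
    return CountMatrix(
        values=counts.values[:, keep],
        gene_ids=counts.gene_ids,
        cell_ids=[c for c, k in zip(counts.cell_ids, keep) if k],
    )


def normalize(counts: CountMatrix) -> NormalizedMatrix:
    """Median-ratio size factors, then log1p of the scaled counts.

    size_factor_c = total_c / median(totals); value = log(1 + count / sf).
    """
    totals = counts.values.sum(axis=0).astype(float)
    if np.any(totals <= 0):
        raise ValueError("cell with zero total count; filter first")
    sf = totals / np.median(totals)
    values = np.log1p(counts.values / sf[None, :])
    return NormalizedMatrix(
        values=values,
        gene_ids=counts.gene_ids,
        cell_ids=counts.cell_ids,
        size_factors=sf,
    )


def select_hvg(norm: NormalizedMatrix, n: int = 5000, n_bins: int = 20) -> np.ndarray:
    """Top-``n`` genes by binned standardized dispersion.

    Genes are binned by mean expression (quantile bins); within each bin the
    dispersion (var/mean) is z-scored and genes with the highest standardized
    dispersion win. Deterministic; ties broken by gene order.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    X = norm.values
    if n >= X.shape[0]:
        return np.arange(X.shape[0])
    means = X.mean(axis=1)
    var = X.var(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        disp = np.where(means > 0, var / means, 0.0)
    # quantile bins on mean expression
    order = np.argsort(means, kind="stable")
    bins = np.empty(X.shape[0], dtype=int)
    bins[order] = np.minimum((np.arange(X.shape[0]) * n_bins) // X.shape[0], n_bins - 1)
    z = np.zeros_like(disp)
    for b in range(n_bins):
        m = bins == b
        if not m.any():
            continue
        mu, sd = disp[m].mean(), disp[m].std()
        z[m] = (disp[m] - mu) / sd if sd > 0 else 0.0
    top = np.argsort(-z, kind="stable")[:n]
    return np.sort(top)


# ---------------------------------------------------------------------------
# ComBat batch correction
# ---------------------------------------------------------------------------

def batch_correct(norm: NormalizedMatrix, batches) -> NormalizedMatrix:
    """Parametric empirical-Bayes location/scale batch adjustment (ComBat).

    Per gene: standardize on the pooled (batch-design) residual variance,
    estimate per-batch location/scale effects, shrink them toward batch-level
    priors (normal prior for location, inverse-gamma for scale, solved by the
    usual fixed-point iteration), remove them, and restore the grand
    mean/variance. The per-gene batch-size-weighted grand mean is restored
    exactly. A single batch is returned unchanged.
    """
    batches = np.asarray(batches)
    if batches.shape[0] != norm.n_cells:
        raise ValueError("one batch label per cell required")
    levels, inverse = np.unique(batches, return_inverse=True)
    sizes = np.bincount(inverse)
    if np.any(sizes < 2):
        small = levels[sizes < 2]
        raise ValueError(f"batches with fewer than 2 cells: {list(small)}")
    X = norm.values
    if len(levels) == 1:
        return NormalizedMatrix(X.copy(), norm.gene_ids, norm.cell_ids, norm.size_factors)

    n = X.shape[1]
    n_batch = len(levels)
    # per-gene batch means and pooled residual variance
    batch_means = np.stack([X[:, inverse == i].mean(axis=1) for i in range(n_batch)], axis=1)
    grand = batch_means @ (sizes / n)
    resid = X - batch_means[:, inverse]
    var_pooled = (resid ** 2).sum(axis=1) / n
    ok = var_pooled > 0
    sd = np.sqrt(np.where(ok, var_pooled, 1.0))

    Z = (X - grand[:, None]) / sd[:, None]
    out = X.copy()

    gamma_hat = np.stack([Z[:, inverse == i].mean(axis=1) for i in range(n_batch)], axis=1)
    delta_hat = np.stack(
        [Z[:, inverse == i].var(axis=1, ddof=1) for i in range(n_batch)], axis=1
    )

    Zadj = np.empty_like(Z)
    for i in range(n_batch):
        g_hat = gamma_hat[ok, i]
        d_hat = np.maximum(delta_hat[ok, i], 1e-12)
        g_bar = g_hat.mean()
        t2 = g_hat.var()
        # inverse-gamma moment-matched prior on the scale effects
        m, s2 = d_hat.mean(), d_hat.var()
        if s2 > 0:
            a_prior = (2 * s2 + m ** 2) / s2
            b_prior = (m * s2 + m ** 3) / s2
        else:
            a_prior, b_prior = 2.0, m
        cells = inverse == i
        Zi = Z[ok][:, cells]
        ni = Zi.shape[1]
        g_star = g_hat.copy()
        d_star = d_hat.copy()
        for _ in range(500):
            g_new = (ni * t2 * g_hat + d_star * g_bar) / (ni * t2 + d_star) if t2 > 0 else np.full_like(g_hat, g_bar)
            ss = ((Zi - g_new[:, None]) ** 2).sum(axis=1)
            d_new = (b_prior + 0.5 * ss) / (ni / 2.0 + a_prior - 1.0)
            d_new = np.maximum(d_new, 1e-12)
            if max(np.max(np.abs(g_new - g_star)), np.max(np.abs(d_new - d_star))) < 1e-10:
                g_star, d_star = g_new, d_new
                break
            g_star, d_star = g_new, d_new
        Zadj[np.ix_(ok, cells)] = (Zi - g_star[:, None]) / np.sqrt(d_star)[:, None]

    out[ok] = Zadj[ok] * sd[ok, None] + grand[ok, None]
    # restore the weighted grand mean exactly
    new_grand = np.stack(
        [out[:, inverse == i].mean(axis=1) for i in range(n_batch)], axis=1
    ) @ (sizes / n)
    out += (grand - new_grand)[:, None]
    return NormalizedMatrix(out, norm.gene_ids, norm.cell_ids, norm.size_factors)


# ---------------------------------------------------------------------------
# Embedding and clustering
# ---------------------------------------------------------------------------

def pca_embed(
    norm: NormalizedMatrix,
    hvg: np.ndarray | None = None,
    n_pcs: int = 15,
    regress_covariate: np.ndarray | None = None,
) -> EmbeddingResult:
    """Center/unit-scale the HVG submatrix, optionally residualize a per-cell
    covariate out of every gene by least squares, then PCA (full SVD)."""
    if n_pcs <= 0:
        raise ValueError("n_pcs must be positive")
    hvg = np.arange(norm.n_genes) if hvg is None else np.asarray(hvg)
    X = norm.values[hvg].T.copy()  # cells x genes
    if regress_covariate is not None:
        cov = np.asarray(regress_covariate, dtype=float)
        if cov.shape[0] != X.shape[0]:
            raise ValueError("covariate length must equal number of cells")
        design = np.column_stack([np.ones_like(cov), cov])
        beta, *_ = np.linalg.lstsq(design, X, rcond=None)
        X = X - design @ beta
    X = X - X.mean(axis=0)
    sdev = X.std(axis=0)
    sdev[sdev == 0] = 1.0
    X = X / sdev
    n_pcs = min(n_pcs, min(X.shape))
    pca = PCA(n_components=n_pcs, svd_solver="full")
    coords = pca.fit_transform(X)
    return EmbeddingResult(
        coordinates=coords,
        loadings=pca.components_.T,
        explained_variance=pca.explained_variance_,
        n_pcs=n_pcs,
        hvg=hvg,
    )


def knn_graph(coords: np.ndarray, k_neighbors: int) -> sparse.csr_matrix:
    """Symmetric KNN similarity graph in embedding space.

    Similarities are a Gaussian kernel with a local bandwidth (distance to the
    k-th neighbour), symmetrized by maximum.
    """
    n = coords.shape[0]
    if k_neighbors >= n:
        raise ValueError("k_neighbors must be < n_cells")
    nn = NearestNeighbors(n_neighbors=k_neighbors + 1).fit(coords)
    dist, idx = nn.kneighbors(coords)
    bw = np.maximum(dist[:, -1], 1e-12)
    rows = np.repeat(np.arange(n), k_neighbors + 1)
    cols = idx.ravel()
    sims = np.exp(-(dist ** 2) / (bw[:, None] ** 2)).ravel()
    keep = rows != cols  # with duplicate points "self" need not come first
    W = sparse.csr_matrix((sims[keep], (rows[keep], cols[keep])), shape=(n, n))
    return W.maximum(W.T)


def cluster_cells(
    embedding: EmbeddingResult,
    k_neighbors: int = 20,
    resolution: float = 0.5,
    seed: int = 0,
) -> ClusterAssignment:
    """Louvain modularity communities on the KNN graph of the embedding,
    relabelled by decreasing size."""
    coords = embedding.coordinates
    if coords.shape[0] < 3:
        raise ValueError("need at least 3 cells to cluster")
    if k_neighbors >= coords.shape[0]:
        raise ValueError("k_neighbors must be < n_cells")
    W = knn_graph(coords, k_neighbors)
    G = nx.from_scipy_sparse_array(W)
    comms = nx.community.louvain_communities(G, resolution=resolution, seed=seed)
    comms = sorted(comms, key=lambda c: (-len(c), min(c)))
    labels = np.empty(coords.shape[0], dtype=int)
    for lab, members in enumerate(comms):
        labels[list(members)] = lab
    return ClusterAssignment(labels=labels, resolution=resolution, k_neighbors=k_neighbors)


# ---------------------------------------------------------------------------
# Signature scoring and compartment correlation
# ---------------------------------------------------------------------------

def signature_score(
    norm: NormalizedMatrix,
    gene_set: list[str],
    control_per_gene: int = 100,
    n_bins: int = 25,
    seed: int = 0,
) -> np.ndarray:
    """Module-score style per-cell score for a gene set.

    Score = mean expression of the set minus mean expression of control genes
    sampled (with a fixed seed) from the same mean-expression bins.
    """
    present = [g for g in gene_set if g in norm.gene_ids]
    if not present:
        raise ValueError("gene set empty or entirely absent")
    rng = np.random.default_rng(seed)
    idx = np.array([norm.gene_ids.index(g) for g in present])
    means = norm.values.mean(axis=1)
    order = np.argsort(means, kind="stable")
    bins = np.empty(norm.n_genes, dtype=int)
    bins[order] = np.minimum((np.arange(norm.n_genes) * n_bins) // norm.n_genes, n_bins - 1)
    controls: list[np.ndarray] = []
    for gi in idx:
        pool = np.where(bins == bins[gi])[0]
        pool = pool[pool != gi]
        if pool.size == 0:
            continue
        take = min(control_per_gene, pool.size)
        controls.append(rng.choice(pool, size=take, replace=False))
    ctrl_idx = np.unique(np.concatenate(controls)) if controls else np.array([], dtype=int)
    score = norm.values[idx].mean(axis=0)
    if ctrl_idx.size:
        score = score - norm.values[ctrl_idx].mean(axis=0)
    return score


def compartment_correlation(
    norm: NormalizedMatrix,
    clusters: ClusterAssignment,
    signature_sets: dict[str, list[str]],
    mode: str = "indicator",
    seed: int = 0,
) -> pd.DataFrame:
    """Cluster x compartment association matrix.

    mode="indicator": Pearson correlation between the cluster centroid
    expression profile and the 0/1 indicator of signature membership.
    mode="score": mean per-cell signature score within each cluster.
    Degenerate (zero-variance) centroids yield NaN entries.
    """
    if clusters.n_clusters < 1 or not signature_sets:
        raise ValueError("need at least one cluster and one signature set")
    n_k = clusters.n_clusters
    out = np.full((n_k, len(signature_sets)), np.nan)
    names = list(signature_sets)
    if mode == "indicator":
        centroids = np.stack(
            [norm.values[:, clusters.labels == k].mean(axis=1) for k in range(n_k)]
        )
        for j, name in enumerate(names):
            ind = np.isin(norm.gene_ids, list(signature_sets[name])).astype(float)
            if ind.std() == 0:
                continue
            for k in range(n_k):
                if centroids[k].std() == 0:
                    continue  # flagged as NaN
                out[k, j] = np.corrcoef(centroids[k], ind)[0, 1]
    elif mode == "score":
        for j, name in enumerate(names):
            sc = signature_score(norm, signature_sets[name], seed=seed)
            for k in range(n_k):
                out[k, j] = sc[clusters.labels == k].mean()
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return pd.DataFrame(out, index=[f"cluster_{k}" for k in range(n_k)], columns=names)


# ---------------------------------------------------------------------------
# Wilcoxon rank-sum differential expression
# ---------------------------------------------------------------------------

def _rank_matrix(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Mid-ranks along axis 1 and the per-row tie correction sum(t^3 - t)."""
    ranks = stats.rankdata(X, axis=1)
    tie_sum = np.zeros(X.shape[0])
    for i in range(X.shape[0]):
        _, cnt = np.unique(X[i], return_counts=True)
        tie_sum[i] = np.sum(cnt ** 3 - cnt)
    return ranks, tie_sum


def rank_sum_p(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Two-sided Wilcoxon rank-sum p-values, one row per gene.

    Exact enumeration of group assignments when both groups have <= 10
    observations; otherwise the tie-corrected normal approximation with
    continuity correction.
    """
    a = np.atleast_2d(a)
    b = np.atleast_2d(b)
    n1, n2 = a.shape[1], b.shape[1]
    pooled = np.concatenate([a, b], axis=1)
    ranks, tie_sum = _rank_matrix(pooled)
    U1 = ranks[:, :n1].sum(axis=1) - n1 * (n1 + 1) / 2.0
    mu = n1 * n2 / 2.0
    if n1 <= 10 and n2 <= 10:
        ps = np.empty(pooled.shape[0])
        n = n1 + n2
        combos = list(itertools.combinations(range(n), n1))
        for i in range(pooled.shape[0]):
            r = ranks[i]
            obs = abs(U1[i] - mu)
            cnt = 0
            for combo in combos:
                u = sum(r[list(combo)]) - n1 * (n1 + 1) / 2.0
                if abs(u - mu) >= obs - 1e-9:
                    cnt += 1
            ps[i] = cnt / len(combos)
        return ps
    n = n1 + n2
    var = n1 * n2 / 12.0 * ((n + 1) - tie_sum / (n * (n - 1)))
    var = np.maximum(var, 1e-300)
    z = (np.abs(U1 - mu) - 0.5) / np.sqrt(var)
    z = np.maximum(z, 0.0)
    p = 2.0 * stats.norm.sf(z)
    return np.minimum(p, 1.0)


def wilcoxon_de(
    norm: NormalizedMatrix,
    group_a: np.ndarray,
    group_b: np.ndarray,
    min_pct: float = 0.25,
    logfc_threshold: float = 0.25,
    pseudocount: float = 1.0,
) -> DifferentialTable:
    """Wilcoxon rank-sum DE between two disjoint cell groups.

    lfc is the natural log of the group mean-expression ratio computed in
    linear (expm1) space with a pseudocount. Genes detected in fewer than
    ``min_pct`` of cells in both groups, or with |lfc| below the threshold,
    are excluded before testing; BH adjustment runs over tested genes only.
    """
    group_a = np.asarray(group_a)
    group_b = np.asarray(group_b)
    if group_a.dtype == bool:
        group_a = np.where(group_a)[0]
    if group_b.dtype == bool:
        group_b = np.where(group_b)[0]
    if len(group_a) < 3 or len(group_b) < 3:
        raise ValueError("both groups need at least 3 cells")
    if set(group_a) & set(group_b):
        raise ValueError("groups overlap")
    A = norm.values[:, group_a]
    B = norm.values[:, group_b]
    pct1 = (A > 0).mean(axis=1)
    pct2 = (B > 0).mean(axis=1)
    mean1 = np.expm1(A).mean(axis=1)
    mean2 = np.expm1(B).mean(axis=1)
    lfc = np.log((mean1 + pseudocount) / (mean2 + pseudocount))
    tested = (np.maximum(pct1, pct2) >= min_pct) & (np.abs(lfc) >= logfc_threshold)
    genes = np.where(tested)[0]
    p = np.full(norm.n_genes, np.nan)
    if genes.size:
        p[genes] = rank_sum_p(A[genes], B[genes])
    p_adj = np.full(norm.n_genes, np.nan)
    if genes.size:
        p_adj[genes] = multipletests(p[genes], method="fdr_bh")[1]
    table = pd.DataFrame(
        {
            "gene": np.asarray(norm.gene_ids)[genes],
            "lfc": lfc[genes],
            "pct1": pct1[genes],
            "pct2": pct2[genes],
            "p": p[genes],
            "p_adj": p_adj[genes],
        }
    )
    return DifferentialTable(table=table)
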