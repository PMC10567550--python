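"""Forward-vs-reverse trajectory comparison.

Differentiating cells (lineage-negative, unwounded, stem-marker low) are
compared with dedifferentiating cells (lineage-positive, wounded, stem-marker
high): genes differentially expressed between the two populations are
retained, their median log-normalized expression is computed in each
population, a loess curve is fitted to the median-median scatter, and the
Pearson correlation R of the median pairs is the reversal statistic. A
strongly negative R says that genes gained during forward differentiation are
lost during dedifferentiation — the reverse-trajectory signature. An
empirical permutation test calibrates R against label shuffles.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.nonparametric.smoothers_lowess import lowess
from statsmodels.stats.multitest import multipletests

from .sc_core import (
    CellAnnotations,
    DifferentialTable,
    NormalizedMatrix,
    rank_sum_p,
    select_hvg,
    wilcoxon_de,
)

__all__ = [
    "ReversalPopulations",
    "ReversalResult",
    "select_populations",
    "reversal_statistic",
    "permutation_test",
    "volcano_table",
]


@dataclass
class ReversalPopulations:
    """Cell index sets for the two trajectory directions (disjoint)."""

    differentiating: np.ndarray  # lineage-negative, day 0, marker < threshold
    dedifferentiating: np.ndarray  # lineage-positive, wounded, marker > threshold
    marker: str = "Lrig1"
    threshold: float = 1.0

    def __post_init__(self) -> None:
        self.differentiating = np.asarray(self.differentiating)
        self.dedifferentiating = np.asarray(self.dedifferentiating)
        if set(self.differentiating) & set(self.dedifferentiating):
            raise ValueError("populations must be disjoint")

    @property
    def sizes(self) -> tuple[int, int]:
        return len(self.differentiating), len(self.dedifferentiating)


@dataclass
class ReversalResult:
    gene_table: pd.DataFrame  # gene, median_diff, median_dediff, lfc, p, p_adj
    loess_curve: pd.DataFrame  # x, y, fitted
    r_pearson: float
    r_spearman: float
    n_genes: int
    permutation_p: float | None = None
    options: dict = field(default_factory=dict)


def select_populations(
    norm: NormalizedMatrix,
    annotations: CellAnnotations,
    marker: str = "Lrig1",
    threshold: float = 1.0,
) -> ReversalPopulations:
    """Gate the two populations on lineage, timepoint and marker expression.

    Strict inequalities on both sides: a cell with marker expression exactly
    at the threshold belongs to neither population.
    """
    gi = norm.gene_index(marker)  # raises KeyError if absent
    meta = annotations.aligned_to(norm.cell_ids)
    expr = norm.values[gi]
    lineage = meta["lineage"].to_numpy()
    tp = meta["timepoint"].to_numpy().astype(int)
    diff = np.where((lineage == "neg") & (tp == 0) & (expr < threshold))[0]
    dediff = np.where((lineage == "pos") & (tp > 0) & (expr > threshold))[0]
    if diff.size == 0:
        raise ValueError("differentiating population is empty")
    if dediff.size == 0:
        raise ValueError("dedifferentiating population is empty")
    return ReversalPopulations(
        differentiating=diff, dedifferentiating=dediff,
        marker=marker, threshold=threshold,
    )


def _median_correlations(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    if x.size < 3:
        raise ValueError("need at least 3 retained genes")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("constant medians in one population; correlation undefined")
    r_p = float(np.corrcoef(x, y)[0, 1])
    r_s = float(stats.spearmanr(x, y).statistic)
    return r_p, r_s


def _retained_genes(
    norm: NormalizedMatrix,
    pops: ReversalPopulations,
    restrict_hvg: bool,
    n_hvg: int,
    adj_p_max: float,
    min_pct: float,
    logfc_threshold: float,
    min_retained: int,
) -> tuple[np.ndarray, DifferentialTable]:
    universe = select_hvg(norm, n=n_hvg) if restrict_hvg else np.arange(norm.n_genes)
    sub = NormalizedMatrix(
        values=norm.values[universe],
        gene_ids=[norm.gene_ids[g] for g in universe],
        cell_ids=norm.cell_ids,
        size_factors=norm.size_factors,
    )
    de = wilcoxon_de(
        sub, pops.dedifferentiating, pops.differentiating,
        min_pct=min_pct, logfc_threshold=logfc_threshold,
    )
    tab = de.table
    sig = tab[tab["p_adj"] < adj_p_max]
    if len(sig) < min_retained:
        sig = tab.nsmallest(min(min_retained, len(tab)), "p")
    keep_names = set(sig["gene"])
    keep = np.array([g for g in universe if norm.gene_ids[g] in keep_names], dtype=int)
    return keep, de


def reversal_statistic(
    pops: ReversalPopulations,
    norm: NormalizedMatrix,
    restrict_hvg: bool = True,
    n_hvg: int = 5000,
    adj_p_max: float = 0.05,
    min_pct: float = 0.25,
    logfc_threshold: float = 0.25,
    min_retained: int = 50,
    loess_span: float = 0.75,
) -> ReversalResult:
    """The reversal correlation statistic.

    (1) restrict to highly variable genes; (2) Wilcoxon DE between the
    populations with BH adjustment; (3) per retained gene, median
    log-normalized expression in each population; (4) loess fit of the
    dedifferentiating medians on the differentiating medians (trend display
    only); (5) R = Pearson correlation of the raw median pairs (Spearman is
    reported alongside). If fewer than ``min_retained`` genes pass the
    adjusted-p filter, the top genes by raw p are retained instead so the
    statistic stays defined on weak-signal data.
    """
    if min(pops.sizes) < 3:
        raise ValueError("both populations need at least 3 cells")
    keep, de = _retained_genes(
        norm, pops, restrict_hvg, n_hvg, adj_p_max, min_pct,
        logfc_threshold, min_retained,
    )
    if keep.size < 3:
        raise ValueError("fewer than 3 retained genes")
    med_diff = np.median(norm.values[np.ix_(keep, pops.differentiating)], axis=1)
    med_dediff = np.median(norm.values[np.ix_(keep, pops.dedifferentiating)], axis=1)
    r_p, r_s = _median_correlations(med_diff, med_dediff)
    fitted = lowess(med_dediff, med_diff, frac=loess_span, xvals=np.sort(med_diff))
    curve = pd.DataFrame({
        "x": np.sort(med_diff),
        "y": med_dediff[np.argsort(med_diff, kind="stable")],
        "fitted": fitted,
    })
    de_idx = de.table.set_index("gene")
    names = [norm.gene_ids[g] for g in keep]
    gene_table = pd.DataFrame({
        "gene": names,
        "median_diff": med_diff,
        "median_dediff": med_dediff,
        "lfc": de_idx.loc[names, "lfc"].to_numpy(),
        "p": de_idx.loc[names, "p"].to_numpy(),
        "p_adj": de_idx.loc[names, "p_adj"].to_numpy(),
    })
    return ReversalResult(
        gene_table=gene_table,
        loess_curve=curve,
        r_pearson=r_p,
        r_spearman=r_s,
        n_genes=int(keep.size),
        options={
            "restrict_hvg": restrict_hvg, "n_hvg": n_hvg, "adj_p_max": adj_p_max,
            "min_pct": min_pct, "logfc_threshold": logfc_threshold,
            "min_retained": min_retained, "loess_span": loess_span,
        },
    )


def _fast_statistic(
    X: np.ndarray,
    idx_diff: np.ndarray,
    idx_dediff: np.ndarray,
    min_pct: float,
    logfc_threshold: float,
    adj_p_max: float,
    min_retained: int,
) -> float | None:
    """Pearson R of median pairs over DE-retained genes; None if undefined.

    Vectorized re-computation used inside the permutation loop (same gene
    retention rule as reversal_statistic, no loess/Spearman)."""
    A = X[:, idx_dediff]
    B = X[:, idx_diff]
    pct1 = (A > 0).mean(axis=1)
    pct2 = (B > 0).mean(axis=1)
    m1 = np.expm1(A).mean(axis=1)
    m2 = np.expm1(B).mean(axis=1)
    lfc = np.log((m1 + 1.0) / (m2 + 1.0))
    tested = (np.maximum(pct1, pct2) >= min_pct) & (np.abs(lfc) >= logfc_threshold)
    genes = np.where(tested)[0]
    if genes.size == 0:
        return None
    p = rank_sum_p(A[genes], B[genes])
    p_adj = multipletests(p, method="fdr_bh")[1]
    sig = genes[p_adj < adj_p_max]
    if sig.size < min_retained:
        order = np.argsort(p, kind="stable")[: min(min_retained, genes.size)]
        sig = genes[order]
    if sig.size < 3:
        return None
    x = np.median(B[sig], axis=1)
    y = np.median(A[sig], axis=1)
    if np.std(x) == 0 or np.std(y) == 0:
        return None
    return float(np.corrcoef(x, y)[0, 1])


def permutation_test(
    pops: ReversalPopulations,
    norm: NormalizedMatrix,
    n_perm: int = 99,
    seed: int = 0,
    restrict_hvg: bool = True,
    n_hvg: int = 5000,
    adj_p_max: float = 0.05,
    min_pct: float = 0.25,
    logfc_threshold: float = 0.25,
    min_retained: int = 50,
) -> tuple[float, float, np.ndarray]:
    """Empirical p-value for the reversal statistic under label shuffles.

    Population labels are permuted over the pooled cells ``n_perm`` times and
    the full statistic (gene retention included) is recomputed each time. The
    test is one-sided in the reversal direction:
    p = (1 + #{R_perm <= R_obs}) / (n_perm + 1). Permutations for which the
    statistic is undefined count against rejection (R_perm treated as <= R_obs).

    Returns (p, R_obs, R_perm array with NaN for undefined permutations).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = np.random.default_rng(seed)
    universe = select_hvg(norm, n=n_hvg) if restrict_hvg else np.arange(norm.n_genes)
    X = norm.values[universe]
    n_diff, n_dediff = pops.sizes
    pooled = np.concatenate([pops.differentiating, pops.dedifferentiating])
    r_obs = _fast_statistic(
        X, pops.differentiating, pops.dedifferentiating,
        min_pct, logfc_threshold, adj_p_max, min_retained,
    )
    if r_obs is None:
        raise ValueError("observed statistic undefined")
    r_perm = np.full(n_perm, np.nan)
    count = 0
    for i in range(n_perm):
        perm = rng.permutation(pooled)
        r = _fast_statistic(
            X, perm[:n_diff], perm[n_diff:],
            min_pct, logfc_threshold, adj_p_max, min_retained,
        )
        if r is None:
            count += 1  # conservative: counts toward the tail
        else:
            r_perm[i] = r
            if r <= r_obs + 1e-12:
                count += 1
    p = (1.0 + count) / (n_perm + 1.0)
    return float(p), float(r_obs), r_perm


def volcano_table(de_table: pd.DataFrame, fc_threshold: float = 1.6) -> pd.DataFrame:
    """Flag genes whose linear fold change exceeds the threshold strictly in
    either direction (ratio > fc_threshold or < 1/fc_threshold)."""
    if isinstance(de_table, DifferentialTable):
        de_table = de_table.table
    out = de_table.copy()
    fc = np.exp(out["lfc"].to_numpy(dtype=float))
    out["fold_change"] = fc
    out["flagged"] = (fc > fc_threshold) | (fc < 1.0 / fc_threshold)
    return out
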