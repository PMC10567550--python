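"""TF→target regulons (TRRUST 4-column dialect) and per-module enrichment.

A regulon is the curated target set of one transcription factor. Module
enrichment uses the hypergeometric upper tail on the module/regulon overlap
within a declared background, BH-adjusted across TFs, with a secondary
effect-size filter on the normalized odds-ratio rank. The second filter is a
configurable stand-in for an undefined tool-specific score and is labelled
non-canonical.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .sc_core import NormalizedMatrix
from .trajectory import PseudotimeVector

__all__ = [
    "RegulonDB",
    "EnrichmentTable",
    "load_regulons",
    "regulon_enrichment",
    "tf_ordered_matrix",
]

MODES = ("Activation", "Repression", "Unknown")


@dataclass
class RegulonDB:
    edges: pd.DataFrame  # tf, target, mode, references
    n_duplicates: int = 0

    def __post_init__(self) -> None:
        if self.edges.duplicated(subset=["tf", "target"]).any():
            raise ValueError("duplicate (tf, target) pairs after load")

    @property
    def tfs(self) -> list[str]:
        return sorted(self.edges["tf"].unique())

    def targets(self, tf: str) -> set[str]:
        return set(self.edges.loc[self.edges["tf"] == tf, "target"])


@dataclass
class EnrichmentTable:
    table: pd.DataFrame  # module, tf, overlap, module_size, regulon_size, p, q, odds_ratio, effect_rank
    q_threshold: float = 0.5
    effect_threshold: float = 0.9

    @property
    def filtered(self) -> pd.DataFrame:
        t = self.table
        return t[(t["q"] < self.q_threshold) & (t["effect_rank"] > self.effect_threshold)]


def load_regulons(path) -> RegulonDB:
    """Parse a 4-column tab-separated TF→target edge list (no header).

    Columns: TF, target, mode (Activation/Repression/Unknown), reference ids.
    Duplicated (tf, target) pairs are dropped (first kept) and counted;
    malformed lines raise with their line number.
    """
    path = Path(path)
    rows = []
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) != 4:
                raise ValueError(f"line {ln}: expected 4 tab-separated columns, got {len(parts)}")
            tf, target, mode, refs = (p.strip() for p in parts)
            if not tf or not target:
                raise ValueError(f"line {ln}: empty gene symbol")
            if mode not in MODES:
                raise ValueError(f"line {ln}: unknown mode {mode!r}")
            rows.append((tf, target, mode, refs))
    df = pd.DataFrame(rows, columns=["tf", "target", "mode", "references"])
    n_dup = int(df.duplicated(subset=["tf", "target"]).sum())
    df = df.drop_duplicates(subset=["tf", "target"], keep="first").reset_index(drop=True)
    return RegulonDB(edges=df, n_duplicates=n_dup)


def hypergeom_enrichment_p(overlap: int, background: int, regulon: int, module: int) -> float:
    """P(X >= overlap) for X ~ Hypergeom(background, regulon, module)."""
    return float(stats.hypergeom.sf(overlap - 1, background, regulon, module))


def regulon_enrichment(
    module_genes,
    db: RegulonDB,
    background,
    q_threshold: float = 0.5,
    effect_threshold: float = 0.9,
    module_name: str = "module",
) -> EnrichmentTable:
    """Hypergeometric TF enrichment of one gene module within a background.

    Only TFs with at least one target in the background are tested. The
    odds ratio uses a Haldane 0.5 correction; ``effect_rank`` is its rank
    among tested TFs scaled to (0, 1].
    """
    background = set(background)
    if not background:
        raise ValueError("empty background")
    module = set(module_genes)
    if not module <= background:
        raise ValueError("module must be a subset of the background")
    N, n_mod = len(background), len(module)
    rows = []
    for tf in db.tfs:
        targets = db.targets(tf) & background
        if not targets:
            continue
        k = len(targets & module)
        K = len(targets)
        p = hypergeom_enrichment_p(k, N, K, n_mod)
        odds = ((k + 0.5) / (n_mod - k + 0.5)) / ((K - k + 0.5) / (N - K - n_mod + k + 0.5))
        rows.append((module_name, tf, k, n_mod, K, p, odds))
    table = pd.DataFrame(
        rows, columns=["module", "tf", "overlap", "module_size", "regulon_size", "p", "odds_ratio"]
    )
    if len(table):
        table["q"] = multipletests(table["p"], method="fdr_bh")[1]
        table["effect_rank"] = table["odds_ratio"].rank(method="average") / len(table)
        table = table.sort_values(["p", "tf"], kind="stable").reset_index(drop=True)
    else:
        table["q"] = pd.Series(dtype=float)
        table["effect_rank"] = pd.Series(dtype=float)
    cols = ["module", "tf", "overlap", "module_size", "regulon_size", "p", "q",
            "odds_ratio", "effect_rank"]
    return EnrichmentTable(table=table[cols], q_threshold=q_threshold,
                           effect_threshold=effect_threshold)


def tf_ordered_matrix(
    norm: NormalizedMatrix,
    tf_list,
    pseudotime: PseudotimeVector,
) -> tuple[pd.DataFrame, list[str]]:
    """TFs x cells expression matrix with columns sorted by ascending
    pseudotime. Missing TF symbols are skipped and returned as warnings."""
    if pseudotime.t.shape[0] != norm.n_cells:
        raise ValueError("pseudotime must be defined for all cells")
    present, missing = [], []
    for tf in tf_list:
        (present if tf in norm.gene_ids else missing).append(tf)
    if not present:
        raise ValueError("no requested TF present in the expression matrix")
    order = np.argsort(pseudotime.t, kind="stable")
    idx = [norm.gene_ids.index(tf) for tf in present]
    mat = pd.DataFrame(
        norm.values[np.ix_(idx, order)],
        index=present,
        columns=[norm.cell_ids[i] for i in order],
    )
    return mat, missing
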