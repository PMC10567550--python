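import numpy as np
import pandas as pd
import pytest

from dediff import sc_core, synth, trajectory


@pytest.fixture(scope="session")
def study_data():
    """One default synthetic study (seed 1) processed through normalization
    and batch correction, with the planted latent coordinate aligned."""
    cfg = synth.default_config(seed=1)
    counts, meta, truth = synth.synth_counts(synth.synth_cells(cfg), cfg)
    filtered = sc_core.filter_cells(counts)
    norm = sc_core.normalize(filtered)
    md = meta.aligned_to(norm.cell_ids)
    corrected = sc_core.batch_correct(norm, md["batch"].to_numpy())
    zfull = pd.Series(truth["z"], index=meta.table["cell_id"])
    z = zfull.loc[norm.cell_ids].to_numpy()
    return {
        "config": cfg,
        "counts": filtered,
        "norm": corrected,
        "norm_uncorrected": norm,
        "meta": md,
        "truth": truth,
        "z": z,
    }


@pytest.fixture(scope="session")
def study_embedding(study_data):
    """PCA embedding, principal graph and smoothed pseudotime on the study."""
    norm = study_data["norm"]
    hvg = sc_core.select_hvg(norm, 5000)
    emb = sc_core.pca_embed(norm, hvg, n_pcs=15)
    graph = trajectory.fit_principal_graph(emb, n_nodes=20, seed=1)
    diff_genes = [g for g in norm.gene_ids if g.startswith(("uHF_", "SD_"))]
    score = sc_core.signature_score(norm, diff_genes, seed=0)
    W = sc_core.knn_graph(emb.coordinates, 20)
    pt = trajectory.compute_pseudotime(graph, emb.coordinates,
                                       root_scores=score, smooth_graph=W)
    return {"hvg": hvg, "embedding": emb, "graph": graph, "knn": W, "pt": pt}


def make_norm(values, gene_ids=None, cell_ids=None):
    values = np.asarray(values, dtype=float)
    g, c = values.shape
    return sc_core.NormalizedMatrix(
        values=values,
        gene_ids=gene_ids or [f"g{i}" for i in range(g)],
        cell_ids=cell_ids or [f"c{i}" for i in range(c)],
        size_factors=np.ones(c),
    )
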