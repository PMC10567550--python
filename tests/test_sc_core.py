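"""Single-cell core stages: QC boundary, normalization algebra, HVG,
ComBat limits, PCA, clustering, scoring and the Wilcoxon DE oracle."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats
from sklearn.metrics import adjusted_rand_score, silhouette_score
from statsmodels.stats.multitest import multipletests

from dediff import sc_core
from dediff.sc_core import (
    CountMatrix, NormalizedMatrix, batch_correct, cluster_cells, filter_cells,
    normalize, pca_embed, rank_sum_p, select_hvg, signature_score,
    compartment_correlation, wilcoxon_de,
)
from conftest import make_norm


def counts_from(values):
    values = np.asarray(values)
    return CountMatrix(values=values,
                       gene_ids=[f"g{i}" for i in range(values.shape[0])],
                       cell_ids=[f"c{i}" for i in range(values.shape[1])])


class TestFilterCells:
    def test_detected_gene_boundary_at_200(self):
        # 199 detected genes -> removed; 200 -> retained (strict "fewer than")
        vals = np.zeros((250, 2), dtype=int)
        vals[:199, 0] = 1
        vals[:200, 1] = 1
        kept = filter_cells(counts_from(vals), min_genes=200)
        assert kept.cell_ids == ["c1"]

    def test_all_above_threshold_identity(self):
        vals = np.ones((5, 4), dtype=int)
        out = filter_cells(counts_from(vals), min_genes=3)
        assert out.cell_ids == [f"c{i}" for i in range(4)]
        assert np.array_equal(out.values, vals)

    def test_empty_matrix_rejected(self):
        with pytest.raises(ValueError):
            filter_cells(counts_from(np.zeros((0, 0), dtype=int)))

    def test_all_cells_removed_rejected(self):
        with pytest.raises(ValueError):
            filter_cells(counts_from(np.zeros((10, 3), dtype=int)), min_genes=1)


class TestNormalize:
    def test_median_total_cell_gets_unit_size_factor(self):
        vals = np.array([[1, 2, 4], [1, 2, 4]])
        norm = normalize(counts_from(vals))
        assert norm.size_factors[1] == pytest.approx(1.0)

    def test_identical_cells_equal_log1p(self):
        vals = np.tile([[3], [7]], (1, 5))
        norm = normalize(counts_from(vals))
        np.testing.assert_allclose(norm.values, np.log1p(vals))

    def test_scaling_one_cell_leaves_normalized_values_unchanged(self):
        rng = np.random.default_rng(0)
        vals = rng.integers(1, 50, size=(20, 7))
        doubled = vals.copy()
        doubled[:, 3] *= 2
        # expm1(value) = count * median_total / total, so dividing out the
        # run-specific median recovers the scale-free profile count/total
        n1, n2 = normalize(counts_from(vals)), normalize(counts_from(doubled))
        m1, m2 = np.median(vals.sum(0)), np.median(doubled.sum(0))
        np.testing.assert_allclose(
            np.expm1(n2.values[:, 3]) / m2, np.expm1(n1.values[:, 3]) / m1,
            rtol=1e-10)
        assert n2.size_factors[3] * m2 == pytest.approx(2 * n1.size_factors[3] * m1)

    def test_zero_total_cell_rejected(self):
        vals = np.array([[1, 0], [2, 0]])
        with pytest.raises(ValueError):
            normalize(counts_from(vals))

    @settings(deadline=None, max_examples=25)
    @given(st.integers(1, 6), st.integers(2, 20))
    def test_scale_invariance_property(self, scale, n_cells):
        rng = np.random.default_rng(42)
        vals = rng.integers(1, 30, size=(10, n_cells))
        scaled = vals.copy()
        scaled[:, 0] *= scale
        n1, n2 = normalize(counts_from(vals)), normalize(counts_from(scaled))
        m1 = np.median(vals.sum(0))
        m2 = np.median(scaled.sum(0))
        np.testing.assert_allclose(np.expm1(n2.values[:, 0]) / m2,
                                   np.expm1(n1.values[:, 0]) / m1, rtol=1e-9)


class TestSelectHvg:
    def test_planted_variable_genes_rank_top(self, study_data):
        hvg = select_hvg(study_data["norm"], n=300)
        names = {study_data["norm"].gene_ids[i] for i in hvg}
        program_genes = {g for prog in study_data["truth"]["programs"].values()
                         for g in prog}
        recovered = len(program_genes & names) / len(program_genes)
        assert recovered > 0.85

    def test_n_larger_than_gene_count_returns_all(self):
        norm = make_norm(np.random.default_rng(0).random((10, 5)))
        assert select_hvg(norm, n=100).size == 10

    def test_deterministic(self, study_data):
        a = select_hvg(study_data["norm"], n=50)
        b = select_hvg(study_data["norm"], n=50)
        assert np.array_equal(a, b)


class TestBatchCorrect:
    def make_shifted(self, n=800, genes=60, noise=0.005, seed=0):
        rng = np.random.default_rng(seed)
        shift = rng.normal(0, 1, genes)
        X = rng.normal(5, noise, (genes, 2 * n))
        X[:, n:] += shift[:, None]
        return make_norm(X), np.array(["a"] * n + ["b"] * n)

    def test_planted_mean_shift_removed_in_large_n_limit(self):
        norm, batches = self.make_shifted()
        out = batch_correct(norm, batches)
        n = len(batches) // 2
        diff = np.abs(out.values[:, :n].mean(1) - out.values[:, n:].mean(1))
        assert diff.max() < 1e-6

    def test_single_batch_identity(self):
        norm, _ = self.make_shifted(n=50)
        out = batch_correct(norm, np.array(["x"] * 100))
        np.testing.assert_allclose(out.values, norm.values, atol=1e-9)

    def test_grand_mean_preserved(self):
        norm, batches = self.make_shifted(n=100)
        out = batch_correct(norm, batches)
        np.testing.assert_allclose(out.values.mean(1), norm.values.mean(1),
                                   atol=1e-9)

    def test_reduces_batch_silhouette_on_planted_shift(self, study_data):
        raw = study_data["norm_uncorrected"]
        cor = study_data["norm"]
        batches = study_data["meta"]["batch"].to_numpy()
        hvg = select_hvg(raw, 200)
        s_raw = silhouette_score(raw.values[hvg].T, batches)
        s_cor = silhouette_score(cor.values[hvg].T, batches)
        assert s_cor < s_raw

    def test_matches_reference_combat_implementation(self):
        scanpy = pytest.importorskip("scanpy")
        import anndata as ad

        rng = np.random.default_rng(3)
        X = rng.normal(0, 1, (40, 120))
        X[:, 60:] += rng.normal(0, 0.8, 40)[:, None]
        X[:, 60:] *= 1.3
        batches = np.array(["a"] * 60 + ["b"] * 60)
        ours = batch_correct(make_norm(X), batches).values
        adata = ad.AnnData(X.T.astype(np.float64))
        adata.obs["batch"] = batches
        scanpy.pp.combat(adata, key="batch")
        theirs = adata.X.T
        # same algorithm family; agree closely apart from our exact grand-mean
        # restoration
        assert np.median(np.abs(ours - theirs)) < 0.05
        assert np.corrcoef(ours.ravel(), theirs.ravel())[0, 1] > 0.999

    def test_undersized_batch_rejected(self):
        norm = make_norm(np.random.default_rng(0).random((5, 4)))
        with pytest.raises(ValueError):
            batch_correct(norm, np.array(["a", "a", "a", "b"]))


class TestPcaEmbed:
    def test_explained_variance_non_increasing(self, study_data):
        emb = pca_embed(study_data["norm"], n_pcs=10)
        assert np.all(np.diff(emb.explained_variance) <= 1e-9)

    def test_rank_one_structure_dominates_pc1(self):
        rng = np.random.default_rng(0)
        u = rng.normal(0, 1, 100)
        v = rng.normal(0, 1, 30)
        X = np.outer(u, v) + rng.normal(0, 1e-3, (100, 30))
        emb = pca_embed(make_norm(np.abs(X)), n_pcs=5)
        frac = emb.explained_variance[0] / emb.explained_variance.sum()
        assert frac > 0.99

    def test_loadings_orthonormal(self, study_data):
        emb = pca_embed(study_data["norm"], n_pcs=8)
        gram = emb.loadings.T @ emb.loadings
        np.testing.assert_allclose(gram, np.eye(8), atol=1e-8)

    def test_covariate_regression_removes_matching_gene(self):
        rng = np.random.default_rng(1)
        X = rng.random((10, 50))
        cov = X[4].copy()
        emb = pca_embed(make_norm(X), n_pcs=3, regress_covariate=cov)
        # residual of gene 4 on the covariate is ~0, so it cannot load on PCs
        resid = X[4] - np.polyval(np.polyfit(cov, X[4], 1), cov)
        assert np.abs(resid).max() < 1e-10

    def test_nonpositive_n_pcs_rejected(self, study_data):
        with pytest.raises(ValueError):
            pca_embed(study_data["norm"], n_pcs=0)


class TestClusterCells:
    @staticmethod
    def blobs(seed=0):
        rng = np.random.default_rng(seed)
        pts = np.vstack([rng.normal(0, 0.3, (60, 5)), rng.normal(5, 0.3, (60, 5))])
        return sc_core.EmbeddingResult(pts, None, np.ones(5), 5, np.arange(5))

    def test_two_separated_blobs_recovered_exactly(self):
        ca = cluster_cells(self.blobs(), k_neighbors=10, resolution=0.5, seed=0)
        assert ca.n_clusters == 2
        assert adjusted_rand_score([0] * 60 + [1] * 60, ca.labels) == 1.0

    def test_resolution_to_zero_single_cluster(self):
        # modularity limit: on a connected graph a vanishing resolution
        # merges everything into one community
        rng = np.random.default_rng(0)
        pts = rng.normal(0, 1, (80, 4))
        emb = sc_core.EmbeddingResult(pts, None, np.ones(4), 4, np.arange(4))
        ca = cluster_cells(emb, k_neighbors=15, resolution=1e-4, seed=0)
        assert ca.n_clusters == 1

    def test_fixed_seed_identical_labels(self):
        a = cluster_cells(self.blobs(), k_neighbors=10, seed=3)
        b = cluster_cells(self.blobs(), k_neighbors=10, seed=3)
        assert np.array_equal(a.labels, b.labels)

    def test_labels_sorted_by_cluster_size(self, study_embedding):
        ca = cluster_cells(study_embedding["embedding"], seed=0)
        sizes = np.bincount(ca.labels)
        assert np.all(np.diff(sizes) <= 0)

    def test_too_few_cells_rejected(self):
        emb = sc_core.EmbeddingResult(np.zeros((2, 3)), None, np.ones(3), 3,
                                      np.arange(3))
        with pytest.raises(ValueError):
            cluster_cells(emb)


class TestSignatureScore:
    def test_planted_up_genes_score_higher_in_differentiated_cells(self, study_data):
        norm, z = study_data["norm"], study_data["z"]
        up = [g for g in norm.gene_ids if g.startswith("uHF_")]
        score = signature_score(norm, up, seed=0)
        hi, lo = score[z > 0.7], score[z < 0.3]
        assert np.median(hi) > np.median(lo)
        assert stats.mannwhitneyu(hi, lo, alternative="two-sided").pvalue < 0.05

    def test_null_gene_set_scores_near_zero(self, study_data):
        norm = study_data["norm"]
        nulls = [g for g in norm.gene_ids if g.startswith("gene_0")][:40]
        score = signature_score(norm, nulls, seed=1)
        assert abs(np.mean(score)) < 3 * np.std(score) / np.sqrt(score.size) + 0.05

    def test_deterministic_given_seed(self, study_data):
        a = signature_score(study_data["norm"], ["Gata6", "Lrig1"], seed=9)
        b = signature_score(study_data["norm"], ["Gata6", "Lrig1"], seed=9)
        np.testing.assert_array_equal(a, b)

    def test_absent_gene_set_rejected(self, study_data):
        with pytest.raises(ValueError):
            signature_score(study_data["norm"], ["nope1", "nope2"])


class TestCompartmentCorrelation:
    def test_cluster_from_program_matches_its_compartment(self, study_data, study_embedding):
        norm, z = study_data["norm"], study_data["z"]
        labels = (z > 0.5).astype(int)  # 0 = stem-like, 1 = differentiated
        clusters = sc_core.ClusterAssignment(labels=labels, resolution=0.5,
                                             k_neighbors=20)
        sigs = {name: list(genes)
                for name, genes in study_data["truth"]["programs"].items()
                if name in ("uHF", "IFE")}
        mat = compartment_correlation(norm, clusters, sigs)
        assert mat.loc["cluster_1"].idxmax() == "uHF"  # up-program
        assert mat.loc["cluster_0"].idxmax() == "IFE"  # down-program
        assert ((mat.fillna(0) <= 1) & (mat.fillna(0) >= -1)).all().all()

    def test_identical_signature_sets_identical_columns(self, study_data):
        norm = study_data["norm"]
        clusters = sc_core.ClusterAssignment(
            labels=np.zeros(norm.n_cells, dtype=int), resolution=0.5,
            k_neighbors=20)
        sigs = {"a": ["Gata6", "Lrig1"], "b": ["Gata6", "Lrig1"]}
        mat = compartment_correlation(norm, clusters, sigs)
        np.testing.assert_allclose(mat["a"], mat["b"])


class TestWilcoxonDE:
    def test_exact_example_disjoint_triples(self):
        # {1,2,3} vs {4,5,6}: U = 0, exact two-sided p = 2/20 = 0.1
        p = rank_sum_p(np.array([[1.0, 2, 3]]), np.array([[4.0, 5, 6]]))[0]
        assert p == pytest.approx(0.1)

    def test_exact_path_matches_bruteforce_enumeration(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            n1, n2 = rng.integers(3, 9, size=2)
            a = rng.integers(0, 5, n1).astype(float)
            b = rng.integers(0, 5, n2).astype(float)
            ours = rank_sum_p(a[None], b[None])[0]
            pooled = np.concatenate([a, b])
            r = stats.rankdata(pooled)
            mu = n1 * n2 / 2
            u_obs = r[:n1].sum() - n1 * (n1 + 1) / 2
            cnt = sum(
                1 for combo in itertools.combinations(range(n1 + n2), int(n1))
                if abs(r[list(combo)].sum() - n1 * (n1 + 1) / 2 - mu)
                >= abs(u_obs - mu) - 1e-9)
            import math
            assert ours == pytest.approx(cnt / math.comb(int(n1 + n2), int(n1)))

    def test_asymptotic_path_matches_scipy(self):
        rng = np.random.default_rng(1)
        a = rng.normal(0, 1, (5, 30))
        b = rng.normal(0.4, 1, (5, 45))
        ours = rank_sum_p(a, b)
        theirs = [stats.mannwhitneyu(a[i], b[i], alternative="two-sided",
                                     method="asymptotic").pvalue
                  for i in range(5)]
        np.testing.assert_allclose(ours, theirs, rtol=1e-10)

    def test_low_detection_gene_excluded(self):
        rng = np.random.default_rng(0)
        vals = rng.random((3, 40)) + 1
        vals[1] = 0.0
        vals[1, :4] = 5.0  # detected in 10% of each group
        norm = make_norm(vals)
        table = wilcoxon_de(norm, np.arange(20), np.arange(20, 40),
                            min_pct=0.25, logfc_threshold=0.0).table
        assert "g1" not in set(table["gene"])

    def test_identical_groups_zero_lfc_excluded(self):
        vals = np.tile(np.linspace(1, 2, 10)[None, :], (4, 1))
        norm = make_norm(np.hstack([vals, vals]))
        table = wilcoxon_de(norm, np.arange(10), np.arange(10, 20)).table
        assert len(table) == 0

    def test_overlapping_groups_rejected(self, study_data):
        with pytest.raises(ValueError):
            wilcoxon_de(study_data["norm"], np.arange(5), np.arange(4, 10))

    def test_global_null_false_positive_rate_controlled(self):
        # 100 replicates of a 200-gene, 2x50-cell null; BH-adjusted
        # rejections at 0.05 stay within binomial slack of the nominal rate
        rng = np.random.default_rng(0)
        n_rej = 0
        n_tot = 0
        for _ in range(100):
            X = rng.poisson(5.0, size=(200, 100)).astype(float)
            norm = make_norm(np.log1p(X))
            t = wilcoxon_de(norm, np.arange(50), np.arange(50, 100),
                            min_pct=0.0, logfc_threshold=0.0).table
            n_rej += int((t["p_adj"] < 0.05).sum())
            n_tot += len(t)
        rate = n_rej / n_tot
        assert rate <= 0.05 + 2 * np.sqrt(0.05 * 0.95 / n_tot)

    @settings(deadline=None, max_examples=20)
    @given(st.lists(st.floats(1e-6, 1.0), min_size=3, max_size=30))
    def test_bh_adjustment_monotone_and_bounded(self, ps):
        adj = multipletests(ps, method="fdr_bh")[1]
        order = np.argsort(ps)
        assert np.all(np.diff(adj[order]) >= -1e-12)
        assert np.all(adj <= 1.0) and np.all(adj >= np.array(ps) - 1e-12)
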