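"""Confounder construction, subsampling, and conditional correlation."""

import numpy as np
import pandas as pd
import pytest

import nichecor as nc
from nichecor.condcor import _cov_to_cor

from conftest import FULL_SPEC, make_tiny_dataset


def ols_residual_cov(Y, X):
    """Independent oracle: covariance of least-squares residuals."""
    Yc = Y - Y.mean(axis=0)
    if X.shape[1] == 0:
        R = Yc
    else:
        Xc = X - X.mean(axis=0)
        beta, *_ = np.linalg.lstsq(Xc, Yc, rcond=None)
        R = Yc - Xc @ beta
    return R.T @ R / (len(Y) - 1)


class TestConfounderMatrix:
    def test_celltype_one_hot(self):
        ds = make_tiny_dataset(4, 2)
        ds.cell_type = np.array(["T-cell", "B-cell", "T-cell", "B-cell"])
        X, names = nc.build_confounder_matrix(ds, nc.ConfounderSpec())
        t_col = X[:, names.index("cell_type:T-cell")]
        np.testing.assert_array_equal(t_col, [1, 0, 1, 0])

    def test_numeric_only(self):
        ds = make_tiny_dataset(4, 2, covariates=pd.DataFrame({"negprobes": [1.0, 2, 3, 4]}))
        spec = nc.ConfounderSpec(use_cell_type=False, numeric_covariates=("negprobes",))
        X, names = nc.build_confounder_matrix(ds, spec)
        assert names == ["negprobes"]
        np.testing.assert_array_equal(X.ravel(), [1, 2, 3, 4])

    def test_keep_all_levels_rows_sum_to_one(self):
        ds = make_tiny_dataset(5, 2)
        ds.cell_type = np.array(["A", "B", "A", "B", "A"])
        X, names = nc.build_confounder_matrix(ds, nc.ConfounderSpec())
        assert X.shape == (5, 2)
        np.testing.assert_array_equal(X.sum(axis=1), np.ones(5))
        np.testing.assert_array_equal(X[:, names.index("cell_type:A")], [1, 0, 1, 0, 1])

    def test_total_counts_derived_when_absent(self):
        ds = make_tiny_dataset(4, 3)
        spec = nc.ConfounderSpec(use_cell_type=False, numeric_covariates=("total_counts",))
        X, _ = nc.build_confounder_matrix(ds, spec)
        np.testing.assert_allclose(X.ravel(), ds.counts_dense().sum(axis=1))

    def test_missing_covariate_fatal(self):
        ds = make_tiny_dataset(4, 2)
        spec = nc.ConfounderSpec(numeric_covariates=("nope",))
        with pytest.raises(nc.DataError, match="nope"):
            nc.build_confounder_matrix(ds, spec)


class TestSubsample:
    def test_small_dataset_identity(self):
        np.testing.assert_array_equal(nc.subsample_cells(100, 5000, 1), np.arange(100))

    def test_deterministic_and_sorted(self):
        a = nc.subsample_cells(10_000, 500, 7)
        b = nc.subsample_cells(10_000, 500, 7)
        np.testing.assert_array_equal(a, b)
        assert (np.diff(a) > 0).all()

    def test_overlap_near_hypergeometric(self):
        n, m = 100_000, 5000
        a = set(nc.subsample_cells(n, m, 1).tolist())
        b = set(nc.subsample_cells(n, m, 2).tolist())
        expected = m * m / n  # 250
        assert abs(len(a & b) - expected) < 5 * np.sqrt(expected)

    def test_max_cells_too_small(self):
        with pytest.raises(nc.ConfigError):
            nc.subsample_cells(10, 1, 0)


class TestConditionalCovariance:
    def test_empty_conditioning_is_covariance(self):
        rng = np.random.default_rng(0)
        Y = rng.normal(size=(50, 4))
        out = nc.conditional_covariance(Y, np.empty((50, 0)))
        np.testing.assert_allclose(out, np.cov(Y.T), atol=1e-12)

    def test_duplicated_column_fully_explained(self):
        rng = np.random.default_rng(1)
        Y = rng.normal(size=(100, 3))
        X = Y[:, [0]].copy()
        out = nc.conditional_covariance(Y, X)
        assert out[0, 0] <= 1e-10

    def test_matches_residual_oracle(self):
        rng = np.random.default_rng(2)
        Y = rng.normal(size=(200, 8))
        X = rng.normal(size=(200, 3))
        out = nc.conditional_covariance(Y, X)
        np.testing.assert_allclose(out, ols_residual_cov(Y, X), atol=1e-8)

    def test_collinear_column_does_not_change_result(self):
        rng = np.random.default_rng(3)
        Y = rng.normal(size=(150, 5))
        X = rng.normal(size=(150, 3))
        X_aug = np.column_stack([X, X @ np.array([1.0, -2.0, 0.5])])
        a = nc.conditional_covariance(Y, X)
        b = nc.conditional_covariance(Y, X_aug)
        np.testing.assert_allclose(a, b, atol=1e-6)

    def test_too_few_rows(self):
        with pytest.raises(nc.DataError, match="3 rows"):
            nc.conditional_covariance(np.zeros((2, 2)), np.zeros((2, 1)))

    def test_symmetry_and_bounds_random_instances(self):
        rng = np.random.default_rng(4)
        for _ in range(20):
            Y = rng.normal(size=(80, 6))
            X = rng.normal(size=(80, 2))
            cov = nc.conditional_covariance(Y, X)
            cor, _ = _cov_to_cor(cov, 1e-12)
            assert np.abs(cor - cor.T).max() <= 1e-10
            assert np.abs(cor).max() <= 1.0 + 1e-10


class TestConditionalCorrelation:
    def test_empty_spec_reduces_to_pearson(self):
        ds = nc.normalize_total_counts(make_tiny_dataset(60, 5, seed=6))
        g = nc.knn_graph(ds.positions, k=5)
        res = nc.conditional_correlation(
            ds, g, nc.ConfounderSpec(use_cell_type=False), max_cells=60, seed=0
        )
        env = nc.environment_sum(g, ds.counts_dense()).dense()
        np.testing.assert_allclose(res.cond_cor, np.corrcoef(env.T), atol=1e-12)

    def test_raw_equals_empty_spec_conditional(self):
        ds = nc.normalize_total_counts(make_tiny_dataset(50, 4, seed=7))
        g = nc.knn_graph(ds.positions, k=4)
        raw = nc.raw_correlation(ds, g, max_cells=50, seed=0)
        cond = nc.conditional_correlation(
            ds, g, nc.ConfounderSpec(use_cell_type=False), max_cells=50, seed=0
        )
        np.testing.assert_allclose(raw.cond_cor, cond.cond_cor, atol=1e-15)

    def test_textbook_pearson_oracle(self):
        ds = nc.normalize_total_counts(make_tiny_dataset(50, 4, seed=8))
        g = nc.knn_graph(ds.positions, k=6)
        res = nc.raw_correlation(ds, g, max_cells=50, seed=0)
        env = nc.environment_sum(g, ds.counts_dense()).dense()
        n = len(env)
        for a in range(4):
            for b in range(4):
                x, y = env[:, a], env[:, b]
                num = ((x - x.mean()) * (y - y.mean())).sum()
                den = np.sqrt(((x - x.mean()) ** 2).sum() * ((y - y.mean()) ** 2).sum())
                assert abs(res.cond_cor[a, b] - num / den) <= 1e-12

    def test_constant_gene_zero_row_flagged(self):
        ds = make_tiny_dataset(40, 3, seed=9)
        ds.counts[:, 2] = 7.0  # constant gene
        g = nc.knn_graph(ds.positions, k=4)
        # skip normalization: constant column must stay constant
        res = nc.conditional_correlation(
            ds, g, nc.ConfounderSpec(use_cell_type=False), max_cells=40, seed=0
        )
        assert "g2" in res.zero_variance_genes
        assert np.all(res.cond_cor[2, :] == 0)

    def test_gene_subset_matches_full_run_submatrix(self):
        ds = nc.normalize_total_counts(make_tiny_dataset(120, 8, seed=10))
        g = nc.knn_graph(ds.positions, k=6)
        spec = nc.ConfounderSpec()
        full = nc.conditional_correlation(ds, g, spec, max_cells=120, seed=1)
        part = nc.conditional_correlation(
            ds, g, spec, max_cells=120, seed=1, genes=["g2", "g5", "g7"]
        )
        pos = full.genes.get_indexer(part.genes)
        np.testing.assert_allclose(
            part.cond_cor, full.cond_cor[np.ix_(pos, pos)], atol=1e-10
        )

    def test_disjoint_gene_subset_fatal(self):
        ds = nc.normalize_total_counts(make_tiny_dataset(30, 3, seed=11))
        g = nc.knn_graph(ds.positions, k=3)
        with pytest.raises(nc.DataError, match="disjoint"):
            nc.conditional_correlation(ds, g, genes=["nope1", "nope2"], max_cells=30)

    def test_spearman_option_runs_and_bounds(self):
        ds = nc.normalize_total_counts(make_tiny_dataset(60, 4, seed=12))
        g = nc.knn_graph(ds.positions, k=5)
        res = nc.conditional_correlation(ds, g, max_cells=60, seed=0, method="spearman")
        assert np.abs(res.cond_cor).max() <= 1.0 + 1e-10

    def test_marker_deflation_small(self, sim_null_10k):
        """Marker genes of spatially clustered types: raw environment
        correlation high, conditional near zero."""
        ds, truth = sim_null_10k
        g = nc.knn_graph(ds.positions, k=50)
        res = nc.conditional_correlation(ds, g, FULL_SPEC, max_cells=3000, seed=0)
        genes = list(res.genes)
        mks = truth.marker_genes["TypeA"][:4]
        for a in range(len(mks)):
            for b in range(a + 1, len(mks)):
                ia, ib = genes.index(mks[a]), genes.index(mks[b])
                assert res.raw_cor[ia, ib] > 0.5
                assert abs(res.cond_cor[ia, ib]) < 0.3


class TestResultInvariants:
    def test_same_subsample_for_raw_and_conditional(self, sim_small_planted):
        ds, _ = sim_small_planted
        ds = nc.normalize_total_counts(ds)
        g = nc.knn_graph(ds.positions, k=20)
        res = nc.conditional_correlation(ds, g, FULL_SPEC, max_cells=1000, seed=3)
        assert res.raw_cor is not None
        assert len(res.subsample_ids) == 1000
        # diagonal is exactly 1 for genes with variance
        d = np.diag(res.cond_cor)
        assert set(np.round(d[d > 0], 12)) == {1.0}
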