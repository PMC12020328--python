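"""Module scores (inverse-sqrt weighting) and cell-type attribution."""

import numpy as np
import pandas as pd
import pytest

import nichecor as nc
from nichecor.modules import Module, ModuleSet
from nichecor.neighbors import EnvironmentMatrix, environment_sum
from nichecor.scoring import _pearson_many

from conftest import make_tiny_dataset


def env_of(values, feature_ids):
    return EnvironmentMatrix(np.asarray(values, dtype=float), list(feature_ids), "test")


class TestGeneWeights:
    def test_unit_mean_gives_unit_weight(self):
        env = env_of(np.ones((10, 1)), ["g"])
        assert nc.gene_weights(env, ["g"]) == {"g": 1.0}

    def test_mean_four_gives_half(self):
        env = env_of(np.full((10, 1), 4.0), ["g"])
        assert nc.gene_weights(env, ["g"])["g"] == pytest.approx(0.5)

    def test_column_mean_oracle(self):
        rng = np.random.default_rng(0)
        vals = rng.poisson(6.0, size=(100, 6)).astype(float) + 0.5
        ids = [f"g{i}" for i in range(6)]
        w = nc.gene_weights(env_of(vals, ids), ids)
        for j, g in enumerate(ids):
            assert w[g] == pytest.approx(vals[:, j].mean() ** -0.5, abs=1e-12)

    def test_zero_mean_gene_excluded(self, caplog):
        env = env_of(np.column_stack([np.ones(5), np.zeros(5)]), ["a", "b"])
        with caplog.at_level("WARNING"):
            w = nc.gene_weights(env, ["a", "b"])
        assert "b" not in w and "a" in w

    def test_unknown_gene_fatal(self):
        with pytest.raises(nc.DataError):
            nc.gene_weights(env_of(np.ones((3, 1)), ["a"]), ["zz"])


class TestModuleScores:
    def _dataset_with_env(self, Y, env_vals, gene_ids):
        ds = make_tiny_dataset(len(Y), len(gene_ids))
        ds.counts = np.asarray(Y, dtype=float)
        ds.gene_ids = pd.Index(gene_ids)
        return ds, env_of(env_vals, gene_ids)

    def test_single_gene_module_equals_column(self):
        Y = np.array([[3.0], [5.0], [7.0]])
        ds, env = self._dataset_with_env(Y, np.ones((3, 1)), ["g"])
        ms = ModuleSet(modules=[Module("g_m", ["g"], np.array([1.0]), 1.0)])
        # single-gene modules are not produced by detection but score fine
        scores = nc.module_scores(ds, env, ms)
        np.testing.assert_allclose(scores.cell_scores[:, 0], Y[:, 0])

    def test_hand_arithmetic(self):
        # env means 4 and 1 give weights 0.5 and 1.0; cell (4, 3) scores 5.0
        Y = np.array([[4.0, 3.0]])
        env_vals = np.array([[4.0, 1.0]])
        ds, env = self._dataset_with_env(Y, env_vals, ["a", "b"])
        ms = ModuleSet(modules=[Module("a_b", ["a", "b"], np.array([1, 1.0]), 1.0)])
        scores = nc.module_scores(ds, env, ms)
        assert scores.cell_scores[0, 0] == pytest.approx(5.0)
        assert scores.weights_used["a_b"] == pytest.approx({"a": 0.5, "b": 1.0})

    def test_weighted_sum_formula(self):
        rng = np.random.default_rng(1)
        Y = rng.poisson(5.0, size=(20, 3)).astype(float)
        env_vals = rng.poisson(20.0, size=(20, 3)).astype(float) + 1
        ds, env = self._dataset_with_env(Y, env_vals, ["a", "b", "c"])
        ms = ModuleSet(modules=[Module("a_b", ["a", "b", "c"], np.ones(3), 1.0)])
        scores = nc.module_scores(ds, env, ms)
        w = np.array([env_vals[:, j].mean() ** -0.5 for j in range(3)])
        np.testing.assert_allclose(scores.cell_scores, (Y * w).sum(axis=1, keepdims=True))
        np.testing.assert_allclose(scores.env_scores, (env_vals * w).sum(axis=1, keepdims=True))

    def test_normalized_weights_option_changes_scale_only(self):
        rng = np.random.default_rng(2)
        Y = rng.poisson(5.0, size=(15, 2)).astype(float)
        env_vals = rng.poisson(20.0, size=(15, 2)).astype(float) + 1
        ds, env = self._dataset_with_env(Y, env_vals, ["a", "b"])
        ms = ModuleSet(modules=[Module("a_b", ["a", "b"], np.ones(2), 1.0)])
        plain = nc.module_scores(ds, env, ms)
        normed = nc.module_scores(ds, env, ms, normalize_weights=True)
        total = sum(plain.weights_used["a_b"].values())
        np.testing.assert_allclose(normed.cell_scores * total, plain.cell_scores)

    def test_linearity_in_expression(self):
        rng = np.random.default_rng(3)
        Y = rng.poisson(5.0, size=(10, 2)).astype(float)
        env_vals = rng.poisson(20.0, size=(10, 2)).astype(float) + 1
        ds, env = self._dataset_with_env(Y, env_vals, ["a", "b"])
        ms = ModuleSet(modules=[Module("a_b", ["a", "b"], np.ones(2), 1.0)])
        base = nc.module_scores(ds, env, ms)
        ds2, env2 = self._dataset_with_env(2 * Y, env_vals, ["a", "b"])
        doubled = nc.module_scores(ds2, env2, ms)
        np.testing.assert_allclose(doubled.cell_scores, 2 * base.cell_scores)

    def test_missing_gene_fatal(self):
        ds, env = self._dataset_with_env(np.ones((3, 1)), np.ones((3, 1)), ["a"])
        ms = ModuleSet(modules=[Module("a_z", ["a", "zz"], np.ones(2), 1.0)])
        with pytest.raises(nc.DataError, match="zz"):
            nc.module_scores(ds, env, ms)


class TestCelltypeEnvExpression:
    def test_single_type_equals_env_column(self):
        ds = make_tiny_dataset(8, 3, seed=4)
        ds.cell_type = np.repeat("A", 8)
        g = nc.knn_graph(ds.positions, k=3)
        vec = nc.celltype_env_expression(ds, g, "g1", "A")
        env = environment_sum(g, ds.counts_dense()).dense()
        np.testing.assert_allclose(vec, env[:, 1])

    def test_partition_identity(self):
        ds = make_tiny_dataset(10, 3, seed=5)
        g = nc.knn_graph(ds.positions, k=4)
        env = environment_sum(g, ds.counts_dense()).dense()
        total = sum(
            nc.celltype_env_expression(ds, g, "g2", c) for c in ("A", "B")
        )
        np.testing.assert_array_equal(total, env[:, 2])

    def test_four_cell_hand_enumeration(self):
        ds = make_tiny_dataset(4, 2)
        ds.counts = np.array([[1.0, 0], [2.0, 0], [4.0, 0], [8.0, 0]])
        ds.cell_type = np.array(["A", "B", "A", "B"])
        graph = nc.NeighborGraph([[1, 2], [0], [3], [2]], "custom", 0, False, 4)
        vec = nc.celltype_env_expression(ds, graph, "g0", "A")
        # N(0)={1(B),2(A)} -> 4; N(1)={0(A)} -> 1; N(2)={3(B)} -> 0; N(3)={2(A)} -> 4
        np.testing.assert_array_equal(vec, [4.0, 1.0, 0.0, 4.0])

    def test_unknown_inputs_fatal(self):
        ds = make_tiny_dataset(4, 2)
        g = nc.knn_graph(ds.positions, k=2)
        with pytest.raises(nc.DataError):
            nc.celltype_env_expression(ds, g, "nope", "A")
        with pytest.raises(nc.DataError):
            nc.celltype_env_expression(ds, g, "g0", "Zed")


class TestAttribution:
    def _scored_fixture(self, seed=6, n=200):
        """Module expressed only where type-1 cells sit in one half of space."""
        rng = np.random.default_rng(seed)
        pos = rng.random((n, 2))
        ct = np.where(rng.random(n) < 0.5, "T1", "T2")
        field = (pos[:, 0] > 0.5).astype(float)
        lam = np.full((n, 3), 1.0)
        lam[:, 0] += 5 * field * (ct == "T1")
        lam[:, 1] += 5 * field * (ct == "T1")
        counts = rng.poisson(lam)
        ds = nc.SpatialDataset(
            counts=counts.astype(float),
            positions=pos,
            cell_type=ct,
            gene_ids=pd.Index(["m0", "m1", "other"]),
            cell_ids=pd.Index([f"c{i}" for i in range(n)]),
        )
        graph = nc.knn_graph(ds.positions, k=10)
        env = environment_sum(graph, ds.counts_dense(), feature_ids=list(ds.gene_ids))
        ms = ModuleSet(modules=[Module("m0_m1", ["m0", "m1"], np.ones(2), 0.5)])
        scores = nc.module_scores(ds, env, ms)
        return ds, graph, ms, scores

    def test_driving_type_scores_highest(self):
        ds, graph, ms, scores = self._scored_fixture()
        table = nc.attribution(ds, graph, ms, scores)
        assert table.celltype_score("m0_m1", "T1") > table.celltype_score("m0_m1", "T2")

    def test_gene_level_matches_loop_oracle(self):
        ds, graph, ms, scores = self._scored_fixture()
        table = nc.attribution(ds, graph, ms, scores)
        for (mod, gene, ct, val) in table.gene_level:
            vec = nc.celltype_env_expression(ds, graph, gene, ct)
            want = np.corrcoef(scores.env_scores[:, 0], vec)[0, 1]
            assert val == pytest.approx(want, abs=1e-10)

    def test_celltype_level_is_exact_max(self):
        ds, graph, ms, scores = self._scored_fixture()
        table = nc.attribution(ds, graph, ms, scores)
        for (mod, ct, val) in table.celltype_level:
            gene_vals = [v for (m, g, c, v) in table.gene_level if m == mod and c == ct]
            assert val == max(gene_vals)

    def test_values_bounded(self):
        ds, graph, ms, scores = self._scored_fixture(seed=7)
        table = nc.attribution(ds, graph, ms, scores)
        assert all(-1 <= v <= 1 for (_, _, _, v) in table.gene_level)

    def test_single_type_reduces_to_plain_correlation(self):
        ds, graph, ms, scores = self._scored_fixture()
        ds.cell_type = np.repeat("T1", ds.n_cells)
        env = environment_sum(graph, ds.counts_dense(), feature_ids=list(ds.gene_ids))
        scores = nc.module_scores(ds, env, ms)
        table = nc.attribution(ds, graph, ms, scores)
        for (mod, gene, ct, val) in table.gene_level:
            j = ds.gene_ids.get_loc(gene)
            want = np.corrcoef(scores.env_scores[:, 0], env.dense()[:, j])[0, 1]
            assert val == pytest.approx(want, abs=1e-10)

    def test_zero_variance_masked_vector_gives_zero(self):
        x = np.arange(5.0)
        Y = np.column_stack([np.ones(5), np.arange(5.0)])
        out = _pearson_many(x, Y)
        assert out[0] == 0.0 and out[1] == pytest.approx(1.0)

    def test_env_scores_consistent_with_adjacency(self):
        ds, graph, ms, scores = self._scored_fixture()
        # env score = adjacency applied to the weighted single-cell expression
        w = scores.weights_used["m0_m1"]
        weighted = sum(
            w[g] * ds.counts_dense()[:, ds.gene_ids.get_loc(g)] for g in ["m0", "m1"]
        )
        expected = graph.adjacency() @ weighted
        np.testing.assert_allclose(scores.env_scores[:, 0], expected, atol=1e-10)
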