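"""Embeddings, differential tables and heat-map data preparation."""

import numpy as np
import pandas as pd
import pytest

from scmpipe import differential, embed, heatmap_data
from scmpipe.errors import InvariantError, LayerError
from scmpipe.model import CellMatrix


def standardized_matrix(values, feature_mz=None):
    values = np.asarray(values, dtype=float)
    n = values.shape[0]
    meta = pd.DataFrame({"cell_id": range(n), "batch": "b0"})
    mz = feature_mz if feature_mz is not None else 100.0 + np.arange(values.shape[1])
    return CellMatrix(values, np.asarray(mz, float), list(range(n)), meta,
                      layer="standardized")


def log_matrix(values):
    m = standardized_matrix(values)
    m.layer = "log"
    m.log_base = np.e
    return m


class TestEmbed:
    def test_pca_on_collinear_rows_has_flat_second_component(self):
        t = np.linspace(0, 1, 10)
        vals = np.outer(t, [1.0, 2.0, -1.0])
        emb = embed(standardized_matrix(vals), "pca")
        assert emb.coordinates[:, 1].var() == pytest.approx(0.0, abs=1e-12)
        evr = emb.params["explained_variance_ratio"]
        assert sum(evr) <= 1 + 1e-9

    def test_tsne_is_deterministic_for_fixed_seed(self):
        rng = np.random.default_rng(0)
        m = standardized_matrix(rng.normal(size=(20, 5)))
        a = embed(m, "tsne", seed=3).coordinates
        b = embed(m, "tsne", seed=3).coordinates
        np.testing.assert_array_equal(a, b)

    def test_kernel_pca_runs_and_is_seed_independent(self):
        rng = np.random.default_rng(1)
        m = standardized_matrix(rng.normal(size=(15, 4)))
        a = embed(m, "kernel_pca", seed=1).coordinates
        b = embed(m, "kernel_pca", seed=99).coordinates
        np.testing.assert_allclose(a, b)

    def test_umap_is_deterministic_for_fixed_seed(self):
        rng = np.random.default_rng(2)
        m = standardized_matrix(rng.normal(size=(25, 6)))
        a = embed(m, "umap", seed=5).coordinates
        b = embed(m, "umap", seed=5).coordinates
        np.testing.assert_array_equal(a, b)

    def test_too_few_cells_rejected(self):
        m = standardized_matrix(np.zeros((2, 3)))
        with pytest.raises(InvariantError, match="3 cells"):
            embed(m, "pca")

    def test_unknown_method_rejected(self):
        m = standardized_matrix(np.zeros((5, 3)))
        with pytest.raises(InvariantError, match="method"):
            embed(m, "sammon")

    def test_requires_standardized_layer(self):
        m = log_matrix(np.random.default_rng(0).normal(size=(5, 3)))
        with pytest.raises(LayerError):
            embed(m, "pca")


class TestDifferential:
    def test_identical_groups_have_zero_fold_change(self):
        rng = np.random.default_rng(3)
        block = rng.normal(5, 1, (6, 7))
        m = log_matrix(np.vstack([block, block]))
        table = differential(m, ["a"] * 6 + ["b"] * 6)
        assert np.abs(table["log2fc"]).max() < 1e-9
        assert (table["p_adjusted"] >= table["p_value"] - 1e-15).all()

    def test_programmed_fourfold_shift_recovered(self):
        # two groups of log-scale values with a true x4 intensity ratio;
        # a single n=30 draw fluctuates, so the recovered fold change is
        # averaged over seeds while significance must hold in every run
        n = 30
        folds = []
        for seed in range(5):
            rng = np.random.default_rng(seed)
            base = rng.lognormal(mean=8.0, sigma=0.3, size=(2 * n, 6))
            base[n:, 0] *= 4.0  # feature 0 shifted x4 in group b
            m = log_matrix(np.log(base + 1.0))
            table = differential(m, ["a"] * n + ["b"] * n)
            folds.append(2 ** table.loc[0, "log2fc"])
            assert table.loc[0, "p_adjusted"] < 0.05
        assert np.mean(folds) == pytest.approx(4.0, abs=0.5)

    def test_benjamini_hochberg_arithmetic(self):
        # independent oracle: BH on p = {.01,.02,.03,.04} over 4 features
        # gives adjusted p = {.04,.04,.04,.04}
        rng = np.random.default_rng(5)
        m = log_matrix(rng.normal(size=(8, 4)))
        table = differential(m, ["a"] * 4 + ["b"] * 4)
        from statsmodels.stats.multitest import multipletests

        expected = multipletests(table["p_value"], method="fdr_bh")[1]
        np.testing.assert_allclose(table["p_adjusted"], expected)
        direct = multipletests([0.01, 0.02, 0.03, 0.04], method="fdr_bh")[1]
        np.testing.assert_allclose(direct, [0.04, 0.04, 0.04, 0.04])

    def test_swapping_groups_negates_fold_change_keeps_p(self):
        rng = np.random.default_rng(6)
        m = log_matrix(rng.normal(size=(12, 5)))
        labels = np.array(["a"] * 6 + ["b"] * 6)
        fwd = differential(m, labels)
        swapped = np.where(labels == "a", "b", "a")
        rev = differential(m, swapped)
        np.testing.assert_allclose(rev["log2fc"], -fwd["log2fc"], atol=1e-12)
        np.testing.assert_allclose(rev["p_value"], fwd["p_value"], atol=1e-12)

    def test_small_group_rejected(self):
        m = log_matrix(np.zeros((5, 3)))
        with pytest.raises(InvariantError, match="at least 3"):
            differential(m, ["a", "a", "b", "b", "b"])

    def test_requires_log_layer(self):
        m = standardized_matrix(np.zeros((6, 3)))
        with pytest.raises(LayerError):
            differential(m, ["a"] * 3 + ["b"] * 3)


class TestHeatmapData:
    def test_top_k_equal_to_n_features_only_reorders(self):
        rng = np.random.default_rng(7)
        m = standardized_matrix(rng.normal(size=(8, 5)))
        hm = heatmap_data(m, 5)
        assert hm.values.shape == (8, 5)
        assert sorted(hm.cell_order.tolist()) == list(range(8))
        assert sorted(hm.feature_order.tolist()) == list(range(5))

    def test_identical_cells_are_adjacent_leaves(self):
        rng = np.random.default_rng(8)
        vals = rng.normal(size=(6, 4))
        vals[4] = vals[1]  # duplicate cell
        hm = heatmap_data(standardized_matrix(vals), 4)
        order = hm.cell_order.tolist()
        assert abs(order.index(1) - order.index(4)) == 1

    def test_block_structure_separates_in_leaf_order(self):
        block_a = np.tile([3.0, 3.0, -3.0, -3.0], (5, 1))
        block_b = -block_a
        rng = np.random.default_rng(9)
        vals = np.vstack([block_a, block_b]) + rng.normal(0, 0.1, (10, 4))
        hm = heatmap_data(standardized_matrix(vals), 4)
        order = hm.cell_order.tolist()
        first_half = set(order[:5])
        assert first_half in ({0, 1, 2, 3, 4}, {5, 6, 7, 8, 9})

    def test_top_k_clamped_with_warning(self):
        rng = np.random.default_rng(10)
        m = standardized_matrix(rng.normal(size=(5, 3)))
        with pytest.warns(UserWarning, match="clamping"):
            hm = heatmap_data(m, 10)
        assert hm.values.shape == (5, 3)

    def test_plot_helpers_render_without_error(self):
        import matplotlib.pyplot as plt

        from scmpipe.plots import embedding_scatter, feature_boxplot, heatmap, volcano

        rng = np.random.default_rng(12)
        m = standardized_matrix(rng.normal(size=(10, 6)))
        emb = embed(m, "pca")
        labels = ["a"] * 5 + ["b"] * 5
        embedding_scatter(emb, labels)
        lm = log_matrix(rng.normal(size=(10, 6)))
        volcano(differential(lm, labels))
        heatmap(heatmap_data(m, 4))
        feature_boxplot(m.values, labels, 0)
        plt.close("all")

    def test_selects_highest_variance_features(self):
        rng = np.random.default_rng(11)
        vals = rng.normal(0, 0.01, (10, 4))
        vals[:, 2] = rng.normal(0, 5.0, 10)
        hm = heatmap_data(standardized_matrix(vals), 1)
        assert hm.feature_mz.tolist() == [102.0]
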