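import numpy as np
import pandas as pd
import pytest

from cortexmx.multivariate import (
    FeatureManifest,
    build_feature_table,
    default_manifests,
    embed,
    manova_canonical,
    pca_variance_cut,
)


class TestManifests:
    def test_default_variable_counts(self):
        m = default_manifests()
        assert len(m["total"].columns) == 21 + 16
        assert len(m["total_14"].columns) == 21 + 14
        assert len(m["neuronal"].columns) == 15 + 9
        assert len(m["neuronal_8"].columns) == 15 + 8
        assert len(m["glial"].columns) == 13 + 6

    def test_manifest_names_every_column(self):
        m = FeatureManifest("x", ("HuD",), ("NeuN",))
        assert m.columns == ["mgi_HuD", "density_NeuN"]


class TestBuildFeatureTable:
    @pytest.fixture()
    def tiny_cells(self):
        return pd.DataFrame(
            {
                "case": ["c1"] * 4 + ["c2"] * 4,
                "area": ["A46"] * 8,
                "layer": ["L4"] * 8,
                "cell_class": ["Neuron"] * 8,
                "HuD_Cell_mgi": [0.2, 0.4, 0.1, 0.3, 1.0, 1.2, 0.9, 1.1],
                "pos_HuD": [True] * 8,
                "layer_area_mm2": [0.1] * 8,
            }
        )

    def test_mean_before_zscoring(self, tiny_cells):
        m = FeatureManifest("t", ("HuD",))
        table = build_feature_table(tiny_cells, m, zscore=False)
        assert table["mgi_HuD"].tolist() == pytest.approx([0.25, 1.05])

    def test_density_feature(self, tiny_cells):
        m = FeatureManifest("t", (), ("HuD",))
        table = build_feature_table(tiny_cells, m, zscore=False)
        assert table["density_HuD"].tolist() == pytest.approx([40.0, 40.0])

    def test_single_field_zscore_degenerate(self, tiny_cells):
        m = FeatureManifest("t", ("HuD",))
        with pytest.raises(ValueError, match="two fields"):
            build_feature_table(tiny_cells[tiny_cells.case == "c1"], m)

    def test_by_cell_type_key_enumeration(self, annotated_cohort):
        cells, _, _ = annotated_cohort
        keep = (~cells["cell_class"].isin(["Other", "Multiple"])) & (
            cells["layer"] != "excluded"
        )
        m = FeatureManifest("t", ("HuD", "GFAP"))
        table = build_feature_table(
            cells[keep], m, by_cell_type=True, zscore=False
        )
        n_keys = cells[keep].groupby(
            ["case", "area", "layer", "cell_class"], observed=True
        ).ngroups
        assert len(table) <= n_keys


class TestPCA:
    def test_single_axis_variance(self):
        rng = np.random.default_rng(0)
        t = rng.normal(size=100)
        X = np.outer(t, [1.0, 2.0, -1.0])
        _, ratio, k = pca_variance_cut(X)
        assert k == 1
        assert ratio[0] == pytest.approx(1.0)

    def test_isotropic_needs_eighty_percent_of_axes(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(20000, 10))
        _, _, k = pca_variance_cut(X, 0.80)
        assert k == 8

    def test_full_variance_target_gives_rank(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(50, 5))
        _, ratio, k = pca_variance_cut(X, 1.0)
        assert k == 5
        assert ratio.sum() == pytest.approx(1.0)

    def test_scores_centered(self):
        rng = np.random.default_rng(3)
        X = rng.normal(5.0, 1.0, size=(100, 4))
        scores, _, _ = pca_variance_cut(X, 0.8)
        assert np.allclose(scores.mean(axis=0), 0.0, atol=1e-9)

    def test_too_few_observations(self):
        with pytest.raises(ValueError):
            pca_variance_cut(np.zeros((1, 3)))


class TestEmbed:
    def test_fixed_seed_reproducible(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(60, 5))
        a = embed(X, seed=9)
        b = embed(X, seed=9)
        assert np.array_equal(a, b)

    def test_planted_clusters_stay_separated(self):
        rng = np.random.default_rng(5)
        X = np.vstack([rng.normal(0, 1, (30, 4)), rng.normal(10, 1, (30, 4))])
        coords = embed(X, seed=0)
        from scipy.spatial.distance import cdist

        a, b = coords[:30], coords[30:]
        within = np.mean([cdist(a, a).mean(), cdist(b, b).mean()])
        between = cdist(a, b).mean()
        assert between / within > 3

    def test_small_n_reduces_perplexity_with_warning(self):
        rng = np.random.default_rng(6)
        X = rng.normal(size=(5, 3))
        with pytest.warns(UserWarning, match="perplexity"):
            coords = embed(X, perplexity=15, seed=1)
        assert coords.shape == (5, 2)

    def test_squared_euclidean_distance_option(self):
        rng = np.random.default_rng(7)
        X = rng.normal(size=(50, 4))
        coords = embed(X, distance="squared-euclidean", seed=2)
        assert coords.shape == (50, 2)


class TestManovaCanonical:
    def test_informative_feature_found(self):
        rng = np.random.default_rng(8)
        X = rng.normal(size=(40, 5))
        g = np.r_[np.zeros(20), np.ones(20)]
        X[g == 1, 2] += 5.0
        res = manova_canonical(X, g, [f"f{i}" for i in range(5)])
        assert res.p_values[0] < 0.05
        assert res.coefficients["c1"].abs().idxmax() == "f2"

    def test_label_permutation_rarely_significant(self):
        rng = np.random.default_rng(9)
        X = rng.normal(size=(40, 5))
        fp = 0
        for _ in range(100):
            g = rng.permutation(np.r_[np.zeros(20), np.ones(20)])
            res = manova_canonical(X, g)
            fp += (res.p_values < 0.05).any()
        assert fp / 100 <= 0.10

    def test_rank_bound_from_collinear_group_means(self):
        rng = np.random.default_rng(10)
        # three group means on a line → at most 2 canonical dims, and the
        # eigenvalue spectrum collapses after the first
        base = rng.normal(size=(30, 4))
        X = np.vstack([base, base + [5, 0, 0, 0], base + [10, 0, 0, 0]])
        g = np.repeat([0, 1, 2], 30)
        res = manova_canonical(X, g)
        assert res.eigenvalues.shape[0] == 2
        assert res.eigenvalues[1] < 0.05 * res.eigenvalues[0]

    def test_sign_invariance_to_feature_reordering(self):
        rng = np.random.default_rng(11)
        X = rng.normal(size=(40, 4))
        g = np.r_[np.zeros(20), np.ones(20)]
        X[g == 1] += [1, 2, 0, -1]
        r1 = manova_canonical(X, g, ["a", "b", "c", "d"])
        perm = [2, 0, 3, 1]
        r2 = manova_canonical(X[:, perm], g, ["c", "a", "d", "b"])
        v1 = r1.coefficients["c1"].reindex(["a", "b", "c", "d"]).to_numpy()
        v2 = r2.coefficients["c1"].reindex(["a", "b", "c", "d"]).to_numpy()
        assert np.allclose(np.abs(v1), np.abs(v2), atol=1e-8)

    def test_newick_dendrogram_contains_all_groups(self):
        rng = np.random.default_rng(12)
        X = rng.normal(size=(60, 3))
        g = np.repeat(["a", "b", "c"], 20)
        X[g == "b"] += 3
        res = manova_canonical(X, g)
        for label in ("a", "b", "c"):
            assert label in res.newick
        assert res.newick.endswith(";")

    def test_degenerate_groups_rejected(self):
        with pytest.raises(ValueError):
            manova_canonical(np.zeros((4, 2)), np.array([0, 0, 0, 0]))
        with pytest.raises(ValueError):
            manova_canonical(np.zeros((3, 2)), np.array([0, 0, 1]))
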