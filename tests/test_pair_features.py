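import itertools

import numpy as np
import pytest

import momentgrn as mg
from momentgrn.pair_features import FeatureError, MomentSpec


def _zmatrix(rows, genes=None):
    rows = np.asarray(rows, dtype=float)
    genes = genes or [f"g{i}" for i in range(rows.shape[0])]
    return mg.ExpressionMatrix(
        genes, [f"s{j}" for j in range(rows.shape[1])], rows, "zscored"
    )


class TestZscore:
    def test_hand_value(self):
        m = mg.ExpressionMatrix(["g"], ["a", "b", "c"], [[1.0, 2.0, 3.0]], "microarray")
        z, excluded = mg.zscore_genes(m)
        np.testing.assert_allclose(
            z.values[0], [-1.22474487, 0.0, 1.22474487], atol=1e-8
        )
        assert excluded == []

    def test_constant_row_dropped(self):
        m = mg.ExpressionMatrix(
            ["flat", "ok"], ["a", "b", "c"], [[5.0, 5.0, 5.0], [1.0, 2.0, 4.0]], "microarray"
        )
        z, excluded = mg.zscore_genes(m)
        assert excluded == ["flat"]
        assert z.gene_ids == ["ok"]

    def test_rows_have_zero_mean_unit_variance(self, small_sim):
        _, _, matrix = small_sim
        z, _ = mg.zscore_genes(matrix)
        np.testing.assert_allclose(z.values.mean(axis=1), 0, atol=1e-9)
        np.testing.assert_allclose(z.values.var(axis=1), 1, atol=1e-9)

    def test_too_few_samples(self):
        m = mg.ExpressionMatrix(["g"], ["a"], [[1.0]], "microarray")
        with pytest.raises(FeatureError):
            mg.zscore_genes(m)


class TestEnumeratePairs:
    def test_counts(self):
        assert len(mg.enumerate_pairs(["a", "b"])) == 1
        assert len(mg.enumerate_pairs([f"g{i}" for i in range(100)])) == 100 * 99 // 2

    def test_matches_brute_force_on_four_genes(self):
        ids = ["d", "b", "a", "c"]
        pairs = mg.enumerate_pairs(ids)
        expected = sorted(
            tuple(sorted(p)) for p in itertools.combinations(ids, 2)
        )
        got = [tuple(p) for p in pairs.pair_ids()]
        assert got == expected
        assert len(got) == 6

    def test_canonical_orientation(self):
        for a, b in mg.enumerate_pairs(["zz", "mm", "aa"]).pair_ids():
            assert a < b

    def test_duplicates_rejected(self):
        with pytest.raises(FeatureError):
            mg.enumerate_pairs(["a", "a", "b"])


class TestMomentSpec:
    def test_default_grid(self):
        spec = MomentSpec()
        assert spec.n_features == 49
        assert spec.orders[0] == (1, 1)
        assert spec.orders[-1] == (7, 7)
        assert spec.column_of(1, 1) == 0
        assert spec.column_of(2, 3) == 9


class TestComputeMoments:
    def test_identical_rows_have_unit_correlation(self):
        x = np.array([-1.0, 0.0, 1.0]) * np.sqrt(1.5)  # exactly z-scored [1,2,3]
        z = _zmatrix([x, x], genes=["a", "b"])
        table = mg.compute_moments(z, mg.enumerate_pairs(["a", "b"]))
        assert table.moment(1, 1)[0] == pytest.approx(1.0, abs=1e-9)
        # m_{2,2} = mean(x^4) = (1.5^2 + 0 + 1.5^2)/3
        assert table.moment(2, 2)[0] == pytest.approx(1.5, abs=1e-9)

    def test_default_width_is_49(self, feature_table):
        table, _ = feature_table
        assert table.raw_moments.shape[1] == 49

    def test_m11_equals_pearson_correlation(self, small_sim):
        _, _, matrix = small_sim
        z, _ = mg.zscore_genes(matrix)
        pairs = mg.enumerate_pairs(z.gene_ids)
        table = mg.compute_moments(z, pairs)
        rng = np.random.default_rng(0)
        rows = z.values
        index = z.gene_index()
        ids = pairs.pair_ids()
        for i in rng.choice(len(pairs), 100, replace=False):
            a, b = ids[i]
            expected = np.corrcoef(rows[index[a]], rows[index[b]])[0, 1]
            assert table.moment(1, 1)[i] == pytest.approx(expected, abs=1e-9)

    def test_agrees_with_naive_double_loop(self, small_sim):
        _, _, matrix = small_sim
        z, _ = mg.zscore_genes(matrix)
        pairs = mg.enumerate_pairs(z.gene_ids)
        table = mg.compute_moments(z, pairs)
        index = z.gene_index()
        ids = pairs.pair_ids()
        rng = np.random.default_rng(1)
        for i in rng.choice(len(pairs), 20, replace=False):
            x = z.values[index[ids[i][0]]]
            y = z.values[index[ids[i][1]]]
            for n in range(1, 8):
                for m in range(1, 8):
                    naive = np.mean(x**n * y**m)
                    assert table.moment(n, m)[i] == pytest.approx(
                        naive, rel=1e-10, abs=1e-10
                    )

    def test_invariant_to_gene_row_order(self, small_sim):
        _, _, matrix = small_sim
        z, _ = mg.zscore_genes(matrix)
        perm = np.random.default_rng(3).permutation(z.n_genes)
        shuffled = mg.ExpressionMatrix(
            [z.gene_ids[i] for i in perm],
            z.sample_ids,
            z.values[perm],
            "zscored",
        )
        pairs = mg.enumerate_pairs(z.gene_ids)
        t1 = mg.compute_moments(z, pairs)
        t2 = mg.compute_moments(shuffled, mg.enumerate_pairs(shuffled.gene_ids))
        np.testing.assert_array_equal(t1.raw_moments, t2.raw_moments)
        np.testing.assert_array_equal(t1.pairs.pair_ids(), t2.pairs.pair_ids())

    def test_missing_gene_named(self):
        z = _zmatrix([[1.0, -1.0]], genes=["a"])
        pairs = mg.enumerate_pairs(["a", "zz"])
        with pytest.raises(FeatureError, match="zz"):
            mg.compute_moments(z, pairs)

    def test_symmetrized_moments_are_orientation_free(self):
        rng = np.random.default_rng(7)
        vals = rng.standard_normal((2, 50))
        vals = (vals - vals.mean(1, keepdims=True)) / vals.std(1, keepdims=True)
        z = _zmatrix(vals, genes=["a", "b"])
        t = mg.compute_moments(z, mg.enumerate_pairs(["a", "b"]), symmetrize=True)
        spec = t.spec
        for n in range(1, 8):
            for m in range(1, 8):
                assert t.moment(n, m)[0] == pytest.approx(t.moment(m, n)[0], abs=1e-12)


class TestStandardize:
    def test_two_value_column(self):
        table = mg.PairFeatureTable(
            pairs=mg.enumerate_pairs(["a", "b", "c"]).subset(np.arange(2)),
            spec=MomentSpec(max_order=1),
            raw_moments=np.array([[1.0], [3.0]]),
        )
        out, means, sds = mg.standardize_moments(table)
        np.testing.assert_allclose(out.raw_moments[:, 0], [-1.0, 1.0])

    def test_idempotent(self, small_sim):
        _, _, matrix = small_sim
        z, _ = mg.zscore_genes(matrix)
        table = mg.compute_moments(z, mg.enumerate_pairs(z.gene_ids))
        once, _, _ = mg.standardize_moments(table)
        twice, _, _ = mg.standardize_moments(once)
        np.testing.assert_allclose(twice.raw_moments, once.raw_moments, atol=1e-12)

    def test_constant_column_zeroed(self):
        table = mg.PairFeatureTable(
            pairs=mg.enumerate_pairs(["a", "b", "c"]),
            spec=MomentSpec(max_order=1),
            raw_moments=np.array([[2.0], [2.0], [2.0]]),
        )
        out, _, sds = mg.standardize_moments(table)
        assert np.all(out.raw_moments == 0)


class TestPCA:
    def test_orthonormal_loadings_and_conserved_variance(self, small_sim):
        _, _, matrix = small_sim
        z, _ = mg.zscore_genes(matrix)
        table = mg.compute_moments(z, mg.enumerate_pairs(z.gene_ids))
        table, _, _ = mg.standardize_moments(table)
        model = mg.fit_pca(table, n_components=49)
        gram = model.loadings.T @ model.loadings
        np.testing.assert_allclose(gram, np.eye(49), atol=1e-8)
        total = table.raw_moments.var(axis=0, ddof=1).sum()
        assert model.explained_variance.sum() == pytest.approx(total, rel=1e-8)
        assert np.all(np.diff(model.explained_variance) <= 1e-10)

    def test_rank_two_data_has_two_components(self):
        rng = np.random.default_rng(0)
        scores = rng.standard_normal((200, 2))
        basis = rng.standard_normal((2, 9))
        data = scores @ basis
        table = mg.PairFeatureTable(
            pairs=mg.enumerate_pairs([f"g{i:03d}" for i in range(21)][:21]).subset(
                np.arange(200)
            ),
            spec=MomentSpec(max_order=3),
            raw_moments=data,
        )
        table, _, _ = mg.standardize_moments(table)
        model = mg.fit_pca(table, n_components=9)
        assert np.all(model.explained_variance[2:] < 1e-10)

    def test_full_reconstruction(self, small_sim):
        _, _, matrix = small_sim
        z, _ = mg.zscore_genes(matrix)
        table = mg.compute_moments(z, mg.enumerate_pairs(z.gene_ids))
        table, _, _ = mg.standardize_moments(table)
        model = mg.fit_pca(table, n_components=49)
        reduced = mg.transform_pca(model, table)
        back = reduced.reduced @ model.loadings.T
        np.testing.assert_allclose(back, table.raw_moments, atol=1e-8)

    def test_default_width_36(self, feature_table):
        table, _ = feature_table
        assert table.reduced.shape[1] == 36

    def test_too_many_components_rejected(self, feature_table):
        table, _ = feature_table
        with pytest.raises(FeatureError):
            mg.fit_pca(table, n_components=50)

    def test_model_round_trip(self, tmp_path, feature_table):
        table, _ = feature_table
        model = mg.fit_pca(table, n_components=5)
        path = tmp_path / "pca.tsv"
        model.write(path)
        back = mg.pair_features.PCAModel.read(path)
        np.testing.assert_allclose(back.loadings, model.loadings, atol=1e-15)
        np.testing.assert_allclose(back.feature_means, model.feature_means)
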