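import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from scbench.data import SCDataset, ValidationError
from scbench.transforms import (Pipeline, Transform, apply_pipeline, default_pipeline,
                                filter_features, log1p, normalize_total, pca_embed,
                                select_top_genes, zscore_scale)


def _ds(X, **kw):
    X = np.asarray(X, float)
    return SCDataset(X=X, cell_ids=[f"c{i}" for i in range(X.shape[0])],
                     gene_ids=[f"g{j}" for j in range(X.shape[1])], **kw)


class TestFilterFeatures:
    def test_drops_unexpressed_gene(self):
        ds = _ds([[1, 0], [2, 0]])
        out = filter_features(ds, min_cells_expressing=1)
        assert out.gene_ids == ["g0"]

    def test_zero_thresholds_identity(self, toy_counts):
        out = filter_features(toy_counts, 0, min_counts=0)
        np.testing.assert_array_equal(out.dense(), toy_counts.dense())

    def test_min_cells_expressing_counts_nonzeros(self):
        # column nonzero counts: g0 -> 2 cells, g1 -> 1 cell
        ds = _ds([[1, 0], [2, 0], [0, 3]])
        out = filter_features(ds, min_cells_expressing=2)
        assert out.gene_ids == ["g0"]

    def test_all_removed_raises(self):
        ds = _ds([[1, 1]])
        with pytest.raises(ValidationError):
            filter_features(ds, min_cells_expressing=2)

    def test_gene_permutation_invariant(self, toy_counts):
        perm = [2, 0, 3, 1]
        shuffled = toy_counts.subset(gene_idx=perm)
        a = filter_features(toy_counts, 2)
        b = filter_features(shuffled, 2)
        assert sorted(a.gene_ids) == sorted(b.gene_ids)


class TestNormalizeTotal:
    def test_row_at_target_unchanged(self):
        out = normalize_total(_ds([[1, 3]]), target_sum=4)
        np.testing.assert_allclose(out.dense(), [[1, 3]])

    def test_scales_to_target(self):
        out = normalize_total(_ds([[1, 3]]), target_sum=1)
        np.testing.assert_allclose(out.dense(), [[0.25, 0.75]])
        assert "normalized" in out.layers

    def test_all_zero_cell_raises(self):
        with pytest.raises(ValidationError, match="filter_features"):
            normalize_total(_ds([[1, 1], [0, 0]]))

    @settings(derandomize=True, max_examples=25, deadline=None)
    @given(st.integers(0, 1000))
    def test_row_sums_property(self, seed):
        rng = np.random.default_rng(seed)
        X = rng.poisson(3.0, size=(5, 8)).astype(float)
        X[:, 0] += 1  # no all-zero cells
        out = normalize_total(_ds(X), target_sum=100.0)
        np.testing.assert_allclose(out.dense().sum(axis=1), 100.0, rtol=1e-9)


def test_log1p_values_and_monotonicity():
    ds = _ds([[0.0, np.e - 1, 7.0, 2.0]])
    out = log1p(ds)
    np.testing.assert_allclose(out.dense()[0, :2], [0.0, 1.0])
    assert np.all(np.argsort(out.dense()[0]) == np.argsort(ds.dense()[0]))


class TestSelectTopGenes:
    def test_k_exceeding_is_identity(self, toy_counts):
        out = select_top_genes(toy_counts, k=10)
        assert out.gene_ids == toy_counts.gene_ids

    def test_totals_ranking_with_tie_break(self):
        # totals 5, 9, 9, 1 -> keep g1, g2 (tie between g1 and g2 irrelevant at k=2)
        X = np.array([[5.0, 9.0, 9.0, 1.0]])
        out = select_top_genes(_ds(X, layers={"raw": X.copy()}), k=2)
        assert out.gene_ids == ["g1", "g2"]

    def test_tie_break_by_gene_id(self):
        X = np.array([[3.0, 3.0, 3.0]])
        out = select_top_genes(_ds(X, layers={"raw": X.copy()}), k=2)
        assert out.gene_ids == ["g0", "g1"]

    def test_default_k_is_3000(self):
        p = default_pipeline("zinb_dec")
        assert p.steps[-1].name == "select_top_genes"
        assert p.steps[-1].params["k"] == 3000

    def test_cell_permutation_invariant(self, toy_counts):
        a = select_top_genes(toy_counts, 2)
        b = select_top_genes(toy_counts.subset(cell_idx=[2, 0, 1]), 2)
        assert a.gene_ids == b.gene_ids


class TestZscore:
    def test_constant_gene_zeroed(self):
        out = zscore_scale(_ds([[2, 1], [2, 3]]))
        np.testing.assert_allclose(out.dense()[:, 0], 0.0)

    def test_population_sd(self):
        out = zscore_scale(_ds([[0, 0], [2, 1]]))
        np.testing.assert_allclose(out.dense()[:, 0], [-1.0, 1.0])

    def test_clip(self):
        X = np.zeros((10, 1))
        X[0, 0] = 100.0
        out = zscore_scale(_ds(X), clip=1.0)
        assert out.dense().max() <= 1.0


class TestPCA:
    def test_rank_one_preserves_distances(self):
        t = np.linspace(0, 1, 6)
        X = np.c_[t, 2 * t]
        Z = pca_embed(_ds(X), d=1)
        D_x = np.abs(t[:, None] - t[None, :]) * np.sqrt(5)
        D_z = np.abs(Z[:, 0][:, None] - Z[:, 0][None, :])
        np.testing.assert_allclose(D_z, D_x, atol=1e-9)

    def test_full_rank_rotation_preserves_distances(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(8, 4))
        Z = pca_embed(_ds(np.abs(X)), d=4)
        A = np.abs(X)

        def pd(M):
            return np.linalg.norm(M[:, None, :] - M[None, :, :], axis=2)

        np.testing.assert_allclose(pd(Z), pd(A), rtol=1e-8, atol=1e-8)

    def test_sign_convention_deterministic(self):
        rng = np.random.default_rng(1)
        X = np.abs(rng.normal(size=(10, 5)))
        np.testing.assert_array_equal(pca_embed(_ds(X), 3, seed=0),
                                      pca_embed(_ds(X), 3, seed=99))

    def test_d_out_of_range(self):
        with pytest.raises(ValueError):
            pca_embed(_ds(np.ones((3, 2))), d=5)


class TestPipeline:
    def test_empty_pipeline_identity(self, toy_counts):
        out = apply_pipeline(Pipeline([]), toy_counts)
        np.testing.assert_array_equal(out.dense(), toy_counts.dense())

    def test_two_step_hand_computation(self):
        p = Pipeline([Transform("normalize_total", {"target_sum": 1.0}),
                      Transform("log1p", {})])
        out = p.apply(_ds([[1, 3]]))
        np.testing.assert_allclose(out.dense(), [[np.log(1.25), np.log(1.75)]])

    def test_json_round_trip_bit_exact(self):
        p = default_pipeline("zinb_dec")
        q = Pipeline.from_json(p.to_json())
        assert q.to_json() == p.to_json()
        assert [s.name for s in q.steps] == [s.name for s in p.steps]

    def test_serialized_pipeline_applies_identically(self, blobs4):
        p = default_pipeline("zinb_dec")
        a = p.apply(blobs4)
        b = Pipeline.from_json(p.to_json()).apply(blobs4)
        np.testing.assert_array_equal(a.dense(), b.dense())

    def test_failing_step_names_index(self):
        p = Pipeline([Transform("log1p", {}), Transform("normalize_total", {})])
        with pytest.raises(ValidationError, match="step 1"):
            p.apply(_ds([[1, 1], [0, 0]]))

    def test_purity_input_unmodified(self, toy_counts):
        snapshot = toy_counts.dense().copy()
        log_len = len(toy_counts.log)
        Pipeline([Transform("normalize_total", {"target_sum": 10.0}),
                  Transform("log1p", {})]).apply(toy_counts)
        np.testing.assert_array_equal(toy_counts.dense(), snapshot)
        assert len(toy_counts.log) == log_len

    def test_unknown_model_rejected(self):
        with pytest.raises(KeyError, match="registered"):
            default_pipeline("nope")

    def test_linear_models_skip_log(self):
        names = [s.name for s in default_pipeline("nnls_deconv").steps]
        assert "log1p" not in names
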