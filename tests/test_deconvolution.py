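import numpy as np
import pytest
from scipy.optimize import nnls as scipy_nnls

from oracles import brute_force_nnls
from scbench.data import get_dataset
from scbench.deconvolution import (NMFConfig, ProportionMatrix, SignatureMatrix,
                                   build_signature, nnls_deconvolve,
                                   score_deconvolution, seeded_nmf_deconvolve)
from scbench.synthetic import SyntheticSpec, mix4_truth, simulate_counts



@pytest.fixture(scope="module")
def reference():
    return simulate_counts(SyntheticSpec(n_cells=150, n_genes=80,
                                         dropout_rate=0.0, seed=21))


@pytest.fixture(scope="module")
def signature(reference):
    return build_signature(reference, n_markers=20)


class TestBuildSignature:
    def test_shapes_and_types(self, signature):
        assert signature.S.shape[1] == 4
        assert len(signature.gene_ids) == signature.S.shape[0]
        assert signature.type_names == ["type0", "type1", "type2", "type3"]

    def test_all_genes_kept_when_markers_exceed(self, reference):
        sig = build_signature(reference, n_markers=10_000)
        assert len(sig.gene_ids) == reference.n_genes

    def test_fold_change_prefers_specific_gene(self):
        import pandas as pd

        from scbench.data import SCDataset
        rng = np.random.default_rng(0)
        X = np.ones((8, 3)) * 5
        X[:4, 0] = 50.0   # gene g0 only high in type A
        X[4:, 0] = 0.0
        X += rng.poisson(0.5, X.shape)
        ids = [f"c{i}" for i in range(8)]
        ds = SCDataset(X=X, cell_ids=ids, gene_ids=["g0", "g1", "g2"],
                       layers={"raw": X.copy()},
                       cell_table=pd.DataFrame({"cell_type": ["A"] * 4 + ["B"] * 4},
                                               index=ids))
        sig = build_signature(ds, n_markers=1)
        assert "g0" in sig.gene_ids

    def test_small_type_rejected(self, reference):
        idx = np.r_[np.flatnonzero(reference.cell_table["cell_type"] == "type0")[:2],
                    np.flatnonzero(reference.cell_table["cell_type"] == "type1")]
        with pytest.raises(ValueError, match="fewer than 3"):
            build_signature(reference.subset(cell_idx=idx), 10)


class TestNNLS:
    def test_exact_recovery_noiseless(self, signature):
        rng = np.random.default_rng(0)
        beta = rng.dirichlet(np.ones(4), size=30)
        Y = beta @ signature.S.T
        pred = nnls_deconvolve(Y, signature)
        assert np.abs(pred.P - beta).max() < 1e-6

    def test_hand_case_active_set(self):
        sig = SignatureMatrix(S=np.array([[1.0, 1.0], [1.0, 0.0]]),
                              gene_ids=["g0", "g1"], type_names=["A", "B"])
        pred = nnls_deconvolve(np.array([[0.0, 1.0]]), sig)
        np.testing.assert_allclose(pred.P, [[1.0, 0.0]], atol=1e-9)

    def test_orthogonal_columns_projection(self):
        sig = SignatureMatrix(S=np.array([[2.0, 0.0], [0.0, 3.0]]),
                              gene_ids=["g0", "g1"], type_names=["A", "B"])
        pred = nnls_deconvolve(np.array([[4.0, 3.0]]), sig)
        np.testing.assert_allclose(pred.P, [[2 / 3, 1 / 3]], atol=1e-9)

    def test_matches_brute_force_and_kkt(self):
        rng = np.random.default_rng(42)
        for _ in range(100):
            k = rng.integers(2, 6)
            g = rng.integers(k + 1, 12)
            A = rng.random((g, k)) * rng.integers(1, 10)
            y = rng.random(g) * 5
            beta, _ = scipy_nnls(A, y)
            _, obj_bf = brute_force_nnls(A, y)
            obj = np.sum((y - A @ beta) ** 2)
            assert obj <= obj_bf + 1e-8
            grad = 2 * A.T @ (A @ beta - y)
            assert np.all(grad[beta > 1e-10] < 1e-6)
            assert np.all(grad[beta <= 1e-10] > -1e-6)

    def test_counting_noise_recovery(self):
        spots = get_dataset("synth_mix4")
        ref = get_dataset("synth_mix4_ref")
        sig = build_signature(ref, 50)
        mse = score_deconvolution(nnls_deconvolve(spots, sig), mix4_truth())
        assert mse <= 0.01

    def test_log_weighting_still_recovers(self):
        spots = get_dataset("synth_mix4")
        ref = get_dataset("synth_mix4_ref")
        sig = build_signature(ref, 50)
        pred = nnls_deconvolve(spots, sig, log_weighting=True)
        assert score_deconvolution(pred, mix4_truth()) <= 0.01

    def test_missing_gene_rejected(self, signature, reference):
        spots = reference.subset(gene_idx=np.arange(5))
        with pytest.raises(ValueError, match="signature genes"):
            nnls_deconvolve(spots, signature)


class TestSeededNMF:
    def test_single_type_spots_recovered(self, reference, signature):
        raw = reference.raw()
        labels = reference.cell_table["cell_type"].to_numpy()
        profiles = np.stack([raw[labels == t].mean(axis=0)
                             for t in signature.type_names])
        profiles *= 1e4 / profiles.sum(axis=1, keepdims=True)
        pure = np.random.default_rng(5).poisson(profiles).astype(float)
        gene_pos = {g: j for j, g in enumerate(reference.gene_ids)}
        Y = pure[:, [gene_pos[g] for g in signature.gene_ids]]
        pred = seeded_nmf_deconvolve(reference, Y, signature, NMFConfig(seed=0))
        assert np.diag(pred.P).min() >= 0.95

    def test_objective_non_increasing(self, reference, signature):
        pred = seeded_nmf_deconvolve(reference, signature.S.T[:1] * 0 + 1.0,
                                     signature, NMFConfig(seed=0, n_iter=50))
        obj = np.array(pred.objectives)
        assert np.all(np.diff(obj) <= 1e-8 * obj[0])

    def test_k_one_reference_like(self, reference, signature):
        # a spot equal to a uniform mixture still yields a simplex row
        pred = seeded_nmf_deconvolve(reference, signature.S.mean(axis=1)[None, :],
                                     signature, NMFConfig(seed=0, n_iter=20))
        np.testing.assert_allclose(pred.P.sum(axis=1), 1.0, atol=1e-9)


class TestScore:
    def test_zero_for_identical(self):
        P = ProportionMatrix(np.array([[0.5, 0.5]]), ["s0"], ["A", "B"])
        assert score_deconvolution(P, P) == 0.0

    def test_uniform_vs_onehot(self):
        a = ProportionMatrix(np.array([[0.5, 0.5]]), ["s0"], ["A", "B"])
        b = ProportionMatrix(np.array([[1.0, 0.0]]), ["s0"], ["A", "B"])
        assert score_deconvolution(a, b) == pytest.approx(0.25)
        assert score_deconvolution(b, a) == pytest.approx(0.25)

    def test_type_misalignment_rejected(self):
        a = ProportionMatrix(np.array([[0.5, 0.5]]), ["s0"], ["A", "B"])
        b = ProportionMatrix(np.array([[0.5, 0.5]]), ["s0"], ["B", "A"])
        with pytest.raises(ValueError, match="type order"):
            score_deconvolution(a, b)
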