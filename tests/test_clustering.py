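import numpy as np
import pytest
from scipy.stats import nbinom

from scbench.clustering import (ConstraintSet, TrainConfig, ZinbParams,
                                fit_graph_ae_cluster, fit_zinb_dec,
                                pairwise_constraint_loss, soft_assignments,
                                target_distribution, zinb_nll)
from scbench.metrics import ari
from scbench.synthetic import SyntheticSpec, simulate_counts
from scbench.transforms import default_pipeline

SMALL_CFG = TrainConfig(seed=0, pretrain_epochs=40, epochs=30)


@pytest.fixture(scope="module")
def small_prepped():
    ds = simulate_counts(SyntheticSpec(n_cells=120, n_genes=80, de_fraction=0.2,
                                       seed=5))
    return default_pipeline("zinb_dec").apply(ds)


class TestZinbNll:
    def test_closed_form_zero_count(self):
        p = ZinbParams(mu=np.array([1.0]), theta=np.array([1.0]), pi=np.array([0.0]))
        assert zinb_nll(np.array([0.0]), p) == pytest.approx(np.log(2), abs=1e-9)

    def test_reduces_to_nb_when_pi_zero(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            x = float(rng.integers(0, 15))
            mu, theta = rng.uniform(0.2, 8.0, 2)
            p = ZinbParams(mu=np.array([mu]), theta=np.array([theta]), pi=np.array([0.0]))
            # scipy NB parameterization: n = theta, p = theta / (theta + mu)
            expected = -nbinom.logpmf(x, theta, theta / (theta + mu))
            assert zinb_nll(np.array([x]), p) == pytest.approx(expected, rel=1e-6)

    def test_dropout_certain_zero(self):
        p = ZinbParams(mu=np.array([5.0]), theta=np.array([1.0]),
                       pi=np.array([1.0 - 1e-12]))
        assert zinb_nll(np.array([0.0]), p) == pytest.approx(0.0, abs=1e-6)

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            zinb_nll(np.array([1.0]), ZinbParams(mu=np.array([np.inf]),
                                                 theta=np.array([1.0]),
                                                 pi=np.array([0.0])))


class TestSoftAssignments:
    def test_single_centroid(self):
        Q = soft_assignments(np.zeros((4, 2)), np.ones((1, 2)))
        np.testing.assert_allclose(Q, 1.0)

    def test_equidistant_symmetry(self):
        Z = np.array([[0.0, 0.0]])
        M = np.array([[1.0, 0.0], [-1.0, 0.0]])
        np.testing.assert_allclose(soft_assignments(Z, M), [[0.5, 0.5]])

    def test_hand_computed_two_centroids(self):
        Z = np.array([[0.0]])
        M = np.array([[0.0], [1.0]])
        np.testing.assert_allclose(soft_assignments(Z, M, alpha=1.0),
                                   [[2 / 3, 1 / 3]], atol=1e-9)

    def test_rows_on_simplex(self):
        rng = np.random.default_rng(0)
        Q = soft_assignments(rng.normal(size=(50, 5)), rng.normal(size=(3, 5)))
        np.testing.assert_allclose(Q.sum(axis=1), 1.0, atol=1e-9)


class TestTargetDistribution:
    def test_symmetric_row_fixed(self):
        np.testing.assert_allclose(target_distribution(np.array([[0.5, 0.5]])),
                                   [[0.5, 0.5]])

    def test_hand_computed(self):
        Q = np.array([[0.9, 0.1], [0.5, 0.5]])
        P = target_distribution(Q)
        np.testing.assert_allclose(P, [[0.972, 0.028], [0.3, 0.7]], atol=1e-9)

    def test_uniform_fixed_point(self):
        Q = np.full((6, 3), 1 / 3)
        np.testing.assert_allclose(target_distribution(Q), Q, atol=1e-12)

    def test_sharpening_under_uniform_frequencies(self):
        # with equal cluster frequencies P preserves the argmax and does not
        # decrease the row maximum
        rng = np.random.default_rng(0)
        for _ in range(1000):
            row = rng.dirichlet(np.ones(4))
            # cyclic shifts give exactly equal cluster frequencies
            Q = np.stack([np.roll(row, s) for s in range(4)])
            P = target_distribution(Q)
            assert P[0].argmax() == row.argmax()
            assert P[0].max() >= row.max() - 1e-12


class TestConstraintLoss:
    def test_identical_one_hot_must_link(self):
        Q = np.array([[1.0, 0.0], [1.0, 0.0]])
        cs = ConstraintSet(must_link=frozenset({(0, 1)}), cannot_link=frozenset())
        assert pairwise_constraint_loss(Q, cs) == pytest.approx(0.0, abs=1e-8)

    def test_orthogonal_one_hot_cannot_link(self):
        Q = np.array([[1.0, 0.0], [0.0, 1.0]])
        cs = ConstraintSet(must_link=frozenset(), cannot_link=frozenset({(0, 1)}))
        assert pairwise_constraint_loss(Q, cs) == pytest.approx(0.0, abs=1e-8)

    def test_uniform_must_link_log2(self):
        Q = np.full((2, 2), 0.5)
        cs = ConstraintSet(must_link=frozenset({(0, 1)}), cannot_link=frozenset())
        assert pairwise_constraint_loss(Q, cs) == pytest.approx(np.log(2), abs=1e-9)

    def test_empty_set_zero(self):
        cs = ConstraintSet(must_link=frozenset(), cannot_link=frozenset())
        assert pairwise_constraint_loss(np.ones((2, 1)), cs) == 0.0

    def test_out_of_range_index(self):
        cs = ConstraintSet(must_link=frozenset({(0, 5)}), cannot_link=frozenset())
        with pytest.raises(IndexError):
            pairwise_constraint_loss(np.ones((2, 1)), cs)

    def test_conflicting_pair_rejected(self):
        with pytest.raises(ValueError):
            ConstraintSet(must_link=frozenset({(0, 1)}),
                          cannot_link=frozenset({(1, 0)}))


class TestFitZinbDec:
    def test_k_equals_one_single_label(self, small_prepped):
        m = fit_zinb_dec(small_prepped, 1, SMALL_CFG)
        assert set(m.predict()) == {0}

    def test_deterministic_under_seed(self, small_prepped):
        m1 = fit_zinb_dec(small_prepped, 3, SMALL_CFG)
        m2 = fit_zinb_dec(small_prepped, 3, SMALL_CFG)
        np.testing.assert_array_equal(m1.predict(), m2.predict())

    def test_k_exceeding_cells_rejected(self, small_prepped):
        with pytest.raises(ValueError):
            fit_zinb_dec(small_prepped, 10_000, SMALL_CFG)

    def test_pretraining_reduces_nll(self):
        for seed in range(5):
            ds = simulate_counts(SyntheticSpec(n_cells=80, n_genes=40, seed=seed))
            dsp = default_pipeline("zinb_dec").apply(ds)
            m = fit_zinb_dec(dsp, 2, TrainConfig(seed=seed, pretrain_epochs=30,
                                                 epochs=1))
            nll = m.history["pretrain_nll"]
            assert nll[-1] < nll[0]

    def test_joint_loss_trend_at_refreshes(self, small_prepped):
        m = fit_zinb_dec(small_prepped, 4,
                         TrainConfig(seed=0, pretrain_epochs=40, epochs=40,
                                     refresh_interval=10))
        losses = m.history["joint_loss"]
        refresh_vals = losses[::10]
        for prev, nxt in zip(refresh_vals, refresh_vals[1:]):
            assert nxt <= prev * 1.05  # non-increasing within 5 %

    def test_recovers_separated_types(self, small_prepped):
        truth = small_prepped.cell_table["cell_type"].to_numpy()
        m = fit_zinb_dec(small_prepped, 4, TrainConfig(seed=0, pretrain_epochs=80,
                                                       epochs=40))
        assert ari(truth, m.predict()) >= 0.8

    def test_score_uses_ari(self, small_prepped):
        m = fit_zinb_dec(small_prepped, 4, SMALL_CFG)
        truth = small_prepped.cell_table["cell_type"].to_numpy()
        assert m.score(small_prepped) == pytest.approx(ari(truth, m.predict(small_prepped)))


class TestFitGraphAE:
    def test_deterministic_and_finite(self, small_prepped):
        m1 = fit_graph_ae_cluster(small_prepped, 4, SMALL_CFG)
        m2 = fit_graph_ae_cluster(small_prepped, 4, SMALL_CFG)
        np.testing.assert_array_equal(m1.predict(), m2.predict())
        Z = m1.embed(small_prepped)
        assert np.all(np.isfinite(Z))
        assert Z.std() > 0

    def test_recovers_separated_types(self, small_prepped):
        truth = small_prepped.cell_table["cell_type"].to_numpy()
        m = fit_graph_ae_cluster(small_prepped, 4, TrainConfig(seed=0, epochs=100))
        assert ari(truth, m.predict()) >= 0.7
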