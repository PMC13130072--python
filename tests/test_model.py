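"""NB likelihood, triplet and cross-entropy losses, forward contracts."""

import numpy as np
import pytest
from scipy import stats

from scges import (
    LossWeights,
    build_model,
    cross_entropy,
    extend_for_query,
    forward,
    nb_log_pmf,
    triplet_loss,
)
from scges.anchors import TripletSet


class TestNbLogPmf:
    def test_zero_count_closed_form(self):
        # x = 0: only the theta-power term survives
        for theta, lib, mu in [(1.0, 1.0, 2.0), (5.0, 3.0, 0.4)]:
            expected = theta * (np.log(theta) - np.log(theta + lib * mu))
            assert nb_log_pmf(0, lib, mu, theta) == pytest.approx(expected)

    def test_geometric_special_case(self):
        # theta = 1 reduces to geometric: pmf(3) = (1/3)(2/3)^3 = 8/81
        assert nb_log_pmf(3, 1.0, 2.0, 1.0) == pytest.approx(
            np.log(8.0 / 81.0), abs=1e-12
        )
        assert nb_log_pmf(3, 1.0, 2.0, 1.0) == pytest.approx(-2.315008, abs=1e-6)

    def test_poisson_limit(self):
        # theta -> inf approaches Poisson; the gap decays like x^2 / theta
        xs = np.arange(21)
        got = nb_log_pmf(xs, 1.0, 5.0, 1e7)
        want = stats.poisson.logpmf(xs, 5.0)
        np.testing.assert_allclose(got, want, atol=1e-4)

    def test_matches_scipy_nbinom(self, rng):
        # independent parameterization: n = theta, p = theta / (theta + mean)
        x = rng.integers(0, 50, size=200)
        lib = rng.uniform(0.5, 2000.0, size=200)
        mu = rng.uniform(1e-4, 0.5, size=200)
        theta = rng.uniform(0.05, 80.0, size=200)
        m = lib * mu
        want = stats.nbinom.logpmf(x, theta, theta / (theta + m))
        np.testing.assert_allclose(nb_log_pmf(x, lib, mu, theta), want, atol=1e-8)

    def test_normalizes_over_support(self):
        for m, theta in [(0.5, 2.0), (5.0, 1.0), (20.0, 10.0), (2.0, 0.3)]:
            xs = np.arange(0, 2000)
            total = np.exp(nb_log_pmf(xs, 1.0, m, theta)).sum()
            assert total >= 0.999

    def test_rejects_invalid_x(self):
        with pytest.raises(ValueError):
            nb_log_pmf(-1, 1.0, 1.0, 1.0)
        with pytest.raises(ValueError):
            nb_log_pmf(1.5, 1.0, 1.0, 1.0)


class TestTripletLoss:
    def _ts(self, triples, margin=1.0):
        return TripletSet(triples=np.asarray(triples), margin=margin)

    def test_hinge_at_zero(self):
        # z_a == z_p and ||z_a - z_n||^2 == margin -> exactly zero
        z = np.array([[0.0, 0.0], [0.0, 0.0], [1.0, 0.0]])
        assert triplet_loss(z, self._ts([[0, 1, 2]])) == 0.0

    def test_degenerate_triple_gives_margin(self):
        z = np.zeros((3, 2))
        assert triplet_loss(z, self._ts([[0, 1, 2]], margin=1.0)) == 1.0

    def test_hand_computed_value(self):
        z = np.array([[0.0, 0.0], [1.0, 0.0], [1.2, 0.0]])
        # max(1 - 1.44 + 1, 0) = 0.56
        assert triplet_loss(z, self._ts([[0, 1, 2]])) == pytest.approx(0.56)

    def test_rigid_motion_invariance(self, rng):
        z = rng.normal(size=(10, 3))
        ts = self._ts([[0, 1, 2], [3, 4, 5], [6, 7, 8]])
        base = triplet_loss(z, ts)
        q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
        moved = z @ q + rng.normal(size=3)
        assert triplet_loss(moved, ts) == pytest.approx(base, abs=1e-9)

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError):
            triplet_loss(np.zeros((2, 2)), self._ts(np.empty((0, 3), int)))


class TestCrossEntropy:
    def test_perfect_prediction_is_zero(self):
        p = np.array([[0.0, 1.0]])
        assert cross_entropy(p, p) == pytest.approx(0.0, abs=1e-9)

    def test_uniform_prediction(self):
        p = np.eye(4)[:1]
        q = np.full((1, 4), 0.25)
        assert cross_entropy(p, q) == pytest.approx(np.log(4.0))

    def test_entropy_identity(self):
        p = np.array([[0.5, 0.5]])
        assert cross_entropy(p, p) == pytest.approx(np.log(2.0))

    def test_gibbs_inequality(self):
        # H(p, q) >= H(p) with equality iff q = p, over a simplex grid
        grid = np.linspace(0.05, 0.95, 10)
        for a in grid:
            p = np.array([[a, 1 - a]])
            hp = cross_entropy(p, p)
            for b in grid:
                q = np.array([[b, 1 - b]])
                assert cross_entropy(p, q) >= hp - 1e-12
                if abs(a - b) > 1e-9:
                    assert cross_entropy(p, q) > hp

    def test_negative_mass_rejected(self):
        with pytest.raises(ValueError):
            cross_entropy(np.array([[-0.1, 1.1]]), np.array([[0.5, 0.5]]))


@pytest.fixture()
def toy_model():
    return build_model(n_hvg=20, n_lvg=30, n_batches=2, n_classes=4,
                       hidden=(16, 8), latent=5, seed=0)


class TestForward:
    def test_output_shapes_and_simplices(self, toy_model, rng):
        x = rng.normal(size=(7, 20))
        s = np.tile([1.0, 0.0], (7, 1))
        z, (mu, theta), probs = forward(toy_model, "hvg", x, s)
        assert z.shape == (7, 5)
        assert mu.shape == theta.shape == (7, 20)
        assert probs.shape == (7, 4)
        np.testing.assert_allclose(mu.sum(axis=1), 1.0, atol=1e-4)
        assert np.all(theta > 0)
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-6)
        # lvg block consumes the joint latent
        x_l = rng.normal(size=(7, 30))
        z_l, (mu_l, _), probs_l = forward(toy_model, "lvg", x_l, s, aux_latent=z)
        assert z_l.shape == (7, 5)
        assert mu_l.shape == (7, 30)
        assert probs_l.shape == (7, 4)

    def test_evaluation_is_bit_deterministic(self, toy_model, rng):
        x = rng.normal(size=(5, 20))
        s = np.tile([0.0, 1.0], (5, 1))
        z1, (mu1, t1), p1 = forward(toy_model, "hvg", x, s)
        z2, (mu2, t2), p2 = forward(toy_model, "hvg", x, s)
        for a, b in [(z1, z2), (mu1, mu2), (t1, t2), (p1, p2)]:
            np.testing.assert_array_equal(a, b)

    def test_batch_code_changes_outputs(self, toy_model, rng):
        x = rng.normal(size=(4, 20))
        s0 = np.tile([1.0, 0.0], (4, 1))
        s1 = np.tile([0.0, 1.0], (4, 1))
        z0, _, _ = forward(toy_model, "hvg", x, s0)
        z1, _, _ = forward(toy_model, "hvg", x, s1)
        assert np.abs(z0 - z1).max() > 1e-8

    def test_lvg_requires_aux_latent(self, toy_model, rng):
        with pytest.raises(ValueError, match="aux_latent"):
            forward(toy_model, "lvg", rng.normal(size=(3, 30)),
                    np.tile([1.0, 0.0], (3, 1)))


class TestExtendForQuery:
    def test_reference_forward_unchanged_after_surgery(self, toy_model, rng):
        x = rng.normal(size=(6, 20))
        s = np.tile([1.0, 0.0], (6, 1))
        before = forward(toy_model, "hvg", x, s)
        extend_for_query(toy_model)
        after = forward(toy_model, "hvg", x, s)
        np.testing.assert_array_equal(before[0], after[0])
        np.testing.assert_array_equal(before[1][0], after[1][0])
        np.testing.assert_array_equal(before[2], after[2])

    def test_query_equals_zero_batch_code_initially(self, toy_model, rng):
        extend_for_query(toy_model)
        x = rng.normal(size=(4, 20))
        s_query = np.tile([0.0, 0.0, 1.0], (4, 1))
        s_zero = np.zeros((4, 3))
        zq, _, _ = forward(toy_model, "hvg", x, s_query)
        z0, _, _ = forward(toy_model, "hvg", x, s_zero)
        np.testing.assert_array_equal(zq, z0)

    def test_double_extension_rejected(self, toy_model):
        extend_for_query(toy_model)
        with pytest.raises(ValueError, match="already"):
            extend_for_query(toy_model)

    def test_original_groups_frozen(self, toy_model):
        extend_for_query(toy_model)
        frozen = [p for k, p in toy_model.params().items()
                  if k in toy_model.frozen]
        assert frozen and all(not p.requires_grad for p in frozen)
        trainable = toy_model.trainable_params()
        assert set(trainable) == {
            "hvg.enc.l1.W_ext", "hvg.dec.l1.W_ext",
            "lvg.enc.l1.W_ext", "lvg.dec.l1.W_ext",
        }
        assert all(np.all(p.data == 0) for p in trainable.values())


class TestLossWeights:
    def test_defaults_and_validation(self):
        w = LossWeights()
        assert (w.alpha, w.beta1, w.beta2, w.beta3) == (1.0, 1.0, 5.0, 1.0)
        with pytest.raises(ValueError):
            LossWeights(alpha=0.0)
        with pytest.raises(ValueError):
            LossWeights(beta1=-1.0)
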