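"""Dual-branch objective: worked examples, oracles, invariants."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from asgbc import nn
from asgbc._autodiff import Tensor
from asgbc.losses import (
    Expander,
    LossWeights,
    PrototypeBank,
    clustering_loss,
    compute_codes,
    contrastive_loss,
    covariance_term,
    expand,
    invariance_term,
    total_loss,
    variance_term,
)


@pytest.fixture
def w():
    return LossWeights()


class TestExpander:
    def test_zero_input_bias_free_gives_zero(self, rng):
        ex = Expander(4, 8, 6, rng, normalize=False)
        for layer in (ex.fc1, ex.fc2, ex.fc3):
            layer.bias.data[...] = 0.0
        assert np.allclose(expand(np.zeros((3, 4)), ex), 0.0)

    def test_affine_parameter_count(self, rng):
        d_in, d_h, d_out = 5, 7, 6
        ex = Expander(d_in, d_h, d_out, rng, normalize=False)
        expected = (d_in * d_h + d_h) + (d_h * d_h + d_h) + (d_h * d_out + d_out)
        assert ex.parameter_count() == expected

    def test_tiny_input_matches_hand_affine_chain(self, rng):
        ex = Expander(2, 2, 1, rng, normalize=False)
        ex.fc1.weight.data = np.array([[1.0, 0.0], [0.0, 2.0]])
        ex.fc1.bias.data = np.array([0.5, -3.0])
        ex.fc2.weight.data = np.array([[2.0, 1.0], [1.0, 0.0]])
        ex.fc2.bias.data = np.array([0.0, 1.0])
        ex.fc3.weight.data = np.array([[1.0], [-1.0]])
        ex.fc3.bias.data = np.array([0.25])
        y = np.array([[1.0, 1.0]])
        # layer 1: (1.5, -1.0) -> relu (1.5, 0); layer 2: (3.0, 2.5) -> relu;
        # layer 3: 3.0 - 2.5 + 0.25 = 0.75
        assert np.allclose(expand(y, ex), [[0.75]], atol=1e-12)


class TestContrastiveTerms:
    def test_invariance_identity_and_pythagoras(self):
        z = np.random.default_rng(0).normal(size=(4, 3))
        assert invariance_term(z, z) == 0.0
        assert invariance_term([[3.0, 4.0]], [[0.0, 0.0]]) == pytest.approx(25.0)

    def test_invariance_matches_loop_oracle_and_symmetry(self, rng):
        z1, z2 = rng.normal(size=(5, 4)), rng.normal(size=(5, 4))
        loop = sum(
            sum((z1[i, j] - z2[i, j]) ** 2 for j in range(4)) for i in range(5)
        ) / 5
        assert invariance_term(z1, z2) == pytest.approx(loop, abs=1e-9)
        assert invariance_term(z1, z2) == invariance_term(z2, z1)

    def test_variance_saturated_hinge(self, w):
        z = np.array([[0.0, 0.0], [2.0, 2.0]])  # column std sqrt(2) >= gamma
        assert variance_term(z, w) == pytest.approx(0.0)

    def test_variance_constant_column(self, w):
        z = np.array([[1.0], [1.0]])
        assert variance_term(z, w) == pytest.approx(1 - np.sqrt(1e-4), abs=1e-12)

    def test_variance_mixed_columns(self, w):
        z = np.array([[0.0, 1.0], [2.0, 1.0]])
        assert variance_term(z, w) == pytest.approx((0.0 + 0.99) / 2, abs=1e-12)

    def test_variance_literal_reading_flag(self):
        w = LossWeights(sqrt_variance=False)
        z = np.array([[1.0], [1.0]])
        assert variance_term(z, w) == pytest.approx(1 - 1e-4, abs=1e-12)

    def test_covariance_uncorrelated_columns(self):
        z = np.array([[1.0, 1.0], [-1.0, 1.0], [1.0, -1.0], [-1.0, -1.0]])
        assert covariance_term(z) == pytest.approx(0.0, abs=1e-12)

    def test_covariance_hand_example(self):
        z = np.array([[1.0, 1.0], [-1.0, -1.0]])
        assert covariance_term(z) == pytest.approx(4.0)

    def test_covariance_matches_loop_oracle(self, rng):
        z = rng.normal(size=(6, 3))
        c = np.cov(z, rowvar=False)
        loop = sum(c[i, j] ** 2 for i in range(3) for j in range(3) if i != j) / 3
        assert covariance_term(z) == pytest.approx(loop, abs=1e-9)

    def test_contrastive_zero_on_ideal_batch(self, w):
        z = np.array([[1.0, 1.0], [-1.0, 1.0], [1.0, -1.0], [-1.0, -1.0]]) * 1.5
        assert contrastive_loss(z, z, w) == pytest.approx(0.0, abs=1e-12)

    def test_contrastive_hand_composition(self, w):
        z = np.array([[1.0, 1.0], [-1.0, -1.0]])
        # s = 0; v = hinge(1 - sqrt(2 + 1e-4)) = 0 per side; c = 4 per side
        assert contrastive_loss(z, z, w) == pytest.approx(8.0, abs=1e-9)

    def test_contrastive_equals_recomposed_terms(self, w, rng):
        z1, z2 = rng.normal(size=(6, 4)), rng.normal(size=(6, 4))
        expected = (
            w.lam * invariance_term(z1, z2)
            + w.mu * (variance_term(z1, w) + variance_term(z2, w))
            + w.nu * (covariance_term(z1) + covariance_term(z2))
        )
        assert contrastive_loss(z1, z2, w) == pytest.approx(expected, abs=1e-9)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_variance_bounded_and_monotone(self, seed):
        w = LossWeights()
        gen = np.random.default_rng(seed)
        base = gen.normal(size=(8, 1))
        values = [
            variance_term(base * scale, w) for scale in (0.1, 0.5, 1.0, 2.0, 5.0)
        ]
        assert all(0.0 <= v <= w.gamma for v in values)
        assert all(a >= b - 1e-12 for a, b in zip(values, values[1:]))

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_covariance_centering_invariance(self, seed):
        gen = np.random.default_rng(seed)
        z = gen.normal(size=(5, 3))
        shift = gen.normal(size=(1, 3))
        assert covariance_term(z) == pytest.approx(covariance_term(z + shift), abs=1e-8)


class TestCodes:
    def test_constant_scores_uniform_codes(self, w):
        q = compute_codes(np.zeros((2, 2)), w)
        assert np.allclose(q, 0.25, atol=1e-12)

    def test_row_marginal_exact_after_final_normalisation(self, w, rng):
        scores = rng.normal(size=(6, 5))
        q = compute_codes(scores, w)
        assert np.all(q >= 0)
        assert np.allclose(q.sum(axis=1), 1 / 6, atol=1e-9)

    def test_matches_long_run_sinkhorn_oracle(self, rng):
        w = LossWeights(eps_ot=0.05, sinkhorn_iters=50)
        scores = rng.normal(size=(3, 3))
        q = compute_codes(scores, w)
        # independent dense Sinkhorn in probability space
        m = np.exp(scores / 0.05)
        for _ in range(50):
            m /= 3 * m.sum(axis=0, keepdims=True)
            m /= 3 * m.sum(axis=1, keepdims=True)
        assert np.allclose(q, m, atol=1e-6)

    def test_column_marginal_tightens_with_iterations(self, rng):
        w3 = LossWeights(eps_ot=0.05, sinkhorn_iters=3)
        w50 = LossWeights(eps_ot=0.05, sinkhorn_iters=50)
        errs = []
        for seed in range(10):
            scores = np.random.default_rng(seed).normal(size=(8, 5))
            errs.append(
                tuple(
                    np.abs(compute_codes(scores, wi).sum(axis=0) - 1 / 5).max()
                    for wi in (w3, w50)
                )
            )
        assert np.mean([e3 for e3, _ in errs]) > np.mean([e50 for _, e50 in errs])


class TestClusteringLoss:
    def make_bank(self, k, d, seed=0, tau=0.1):
        return PrototypeBank(k, d, np.random.default_rng(seed), tau=tau)

    def test_symmetry_under_identical_views(self, w, rng):
        y = rng.normal(size=(4, 6))
        bank = self.make_bank(5, 6)
        scores = (y / np.linalg.norm(y, axis=1, keepdims=True)) @ (
            bank.vectors.data / np.linalg.norm(bank.vectors.data, axis=1, keepdims=True)
        ).T
        q = compute_codes(scores, w)
        from asgbc.losses import _swapped_side

        one_side = _swapped_side(Tensor(scores), q, bank.tau).item()
        assert clustering_loss(y, y, bank, w) == pytest.approx(2 * one_side, abs=1e-9)

    def test_uniform_case_attains_entropy_lower_bound(self):
        """One sample, two equidistant prototypes: p matches the rescaled codes
        (0.5, 0.5) row-wise, so each side equals their entropy, log 2."""
        w = LossWeights(sinkhorn_iters=50)
        bank = self.make_bank(2, 2)
        bank.vectors.data = np.array([[1.0, 0.0], [0.0, 1.0]])
        y = np.array([[1.0, 1.0]])  # equal cosine to both prototypes
        assert clustering_loss(y, y, bank, w) == pytest.approx(2 * np.log(2), abs=1e-9)

    def test_matches_loop_cross_entropy_oracle(self, w, rng):
        y1, y2 = rng.normal(size=(4, 6)), rng.normal(size=(4, 6))
        bank = self.make_bank(5, 6, seed=3)
        cn = bank.vectors.data / np.linalg.norm(bank.vectors.data, axis=1, keepdims=True)

        def side(y, q):
            yn = y / np.linalg.norm(y, axis=1, keepdims=True)
            s = yn @ cn.T / bank.tau
            p = np.exp(s - s.max(axis=1, keepdims=True))
            p /= p.sum(axis=1, keepdims=True)
            total = 0.0
            for i in range(len(y)):
                for k in range(5):
                    total -= 4 * q[i, k] * np.log(p[i, k])
            return total / 4

        def scores(y):
            yn = y / np.linalg.norm(y, axis=1, keepdims=True)
            return yn @ cn.T

        q1 = compute_codes(scores(y1), w)
        q2 = compute_codes(scores(y2), w)
        expected = side(y1, q2) + side(y2, q1)
        assert clustering_loss(y1, y2, bank, w) == pytest.approx(expected, abs=1e-9)

    def test_zero_norm_rows_rejected(self, w):
        bank = self.make_bank(3, 2)
        with pytest.raises(ValueError):
            clustering_loss(np.zeros((2, 2)), np.ones((2, 2)), bank, w)

    def test_gradient_step_decreases_loss(self, w, rng):
        backbone_out = Tensor(rng.normal(size=(8, 4)), requires_grad=True)
        bank = self.make_bank(3, 4, seed=1)
        opt = nn.Adam([backbone_out, bank.vectors], lr=0.05)
        first = None
        for _ in range(5):
            loss = clustering_loss(backbone_out, backbone_out, bank, w)
            if first is None:
                first = loss.item()
            opt.zero_grad()
            loss.backward()
            opt.step()
        final = clustering_loss(backbone_out, backbone_out, bank, w).item()
        assert final < first


class TestTotalLoss:
    def test_weighted_sum_arithmetic(self, w, rng):
        y1, y2 = rng.normal(size=(4, 6)), rng.normal(size=(4, 6))
        z1, z2 = rng.normal(size=(4, 8)), rng.normal(size=(4, 8))
        bank = PrototypeBank(5, 6, np.random.default_rng(2))
        expected = contrastive_loss(z1, z2, w) + w.alpha * clustering_loss(y1, y2, bank, w)
        assert total_loss(y1, y2, z1, z2, bank, w) == pytest.approx(expected, abs=1e-9)

    def test_alpha_zero_reduces_to_contrastive(self, rng):
        w = LossWeights(alpha=0.0)
        y1, y2 = rng.normal(size=(4, 6)), rng.normal(size=(4, 6))
        z1, z2 = rng.normal(size=(4, 8)), rng.normal(size=(4, 8))
        bank = PrototypeBank(5, 6, np.random.default_rng(2))
        assert total_loss(y1, y2, z1, z2, bank, w) == pytest.approx(
            contrastive_loss(z1, z2, w), abs=1e-12
        )
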