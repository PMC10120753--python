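"""Joint latent-dimension distributions and the contrastive loss."""

import numpy as np
import pytest

from clclsa.contrastive import (
    JointDistribution,
    joint_distribution,
    latents_to_distributions,
    multi_omics_contrastive_loss,
    pair_contrastive_loss,
    pair_contrastive_loss_t,
)
from clclsa.nn import Tensor
from tests.test_cross_omics import make_bundle

LN3 = float(np.log(3.0))


def brute_force_loss(p: np.ndarray, alpha: float) -> float:
    """Scalar double-loop reference for the contrastive loss."""
    row = p.sum(axis=1)
    col = p.sum(axis=0)
    total = 0.0
    for d in range(p.shape[0]):
        for dp in range(p.shape[1]):
            if p[d, dp] <= 0:
                continue
            total -= p[d, dp] * np.log(
                p[d, dp] / (row[d] ** (alpha + 1) * col[dp] ** (alpha + 1))
            )
    return total


def random_stochastic(rng, n, d):
    raw = rng.random((n, d)) + 1e-3
    return raw / raw.sum(axis=1, keepdims=True)


class TestLatentsToDistributions:
    def test_uniform_on_equal_logits(self):
        out = latents_to_distributions(np.array([[0.0, 0.0]]))
        np.testing.assert_allclose(out.data, [[0.5, 0.5]])

    def test_hand_computed_softmax(self):
        out = latents_to_distributions(np.array([[LN3, 0.0]]))
        np.testing.assert_allclose(out.data, [[0.75, 0.25]], atol=1e-12)

    def test_shift_invariance(self, rng):
        z = rng.normal(size=(4, 5))
        a = latents_to_distributions(z).data
        b = latents_to_distributions(z + 3.7).data
        np.testing.assert_allclose(a, b, atol=1e-12)


class TestJointDistribution:
    def test_single_subject_outer_product(self):
        jd = joint_distribution(np.array([[1.0, 0.0]]), np.array([[1.0, 0.0]]))
        np.testing.assert_allclose(jd.P, [[1.0, 0.0], [0.0, 0.0]])
        np.testing.assert_allclose(jd.row_marginals, [1.0, 0.0])
        np.testing.assert_allclose(jd.col_marginals, [1.0, 0.0])

    def test_uniform_rows_give_uniform_joint(self):
        s = np.full((3, 4), 0.25)
        jd = joint_distribution(s, s)
        np.testing.assert_allclose(jd.P, 1.0 / 16)

    def test_sums_to_one_for_random_inputs(self, rng):
        for _ in range(20):
            si = random_stochastic(rng, 6, 4)
            sk = random_stochastic(rng, 6, 4)
            jd = joint_distribution(si, sk)
            assert jd.P.sum() == pytest.approx(1.0, abs=1e-9)
            assert (jd.P >= 0).all()

    def test_subject_count_mismatch(self, rng):
        with pytest.raises(ValueError, match="subject"):
            joint_distribution(random_stochastic(rng, 3, 4), random_stochastic(rng, 4, 4))

    def test_negative_entries_rejected(self):
        with pytest.raises(ValueError, match="non-negative"):
            JointDistribution(np.array([[1.5, -0.5], [0.0, 0.0]]))


class TestPairLoss:
    def test_degenerate_single_dimension_is_zero(self):
        jd = JointDistribution(np.array([[1.0]]))
        for alpha in (0.0, 1.0, 9.0):
            assert pair_contrastive_loss(jd, alpha) == pytest.approx(0.0)

    @pytest.mark.parametrize("d", [2, 4, 8])
    @pytest.mark.parametrize("alpha", [0.0, 1.0, 9.0])
    def test_uniform_closed_form(self, d, alpha):
        """Uniform joint: loss = -2 * alpha * ln d exactly."""
        jd = JointDistribution(np.full((d, d), 1.0 / d**2))
        expected = -2.0 * alpha * np.log(d)
        assert pair_contrastive_loss(jd, alpha) == pytest.approx(expected, abs=1e-10)

    def test_independence_with_zero_alpha_is_zero(self, rng):
        p = np.array([0.2, 0.5, 0.3])
        q = np.array([0.6, 0.4])
        jd = JointDistribution(np.outer(p, q))
        assert pair_contrastive_loss(jd, 0.0) == pytest.approx(0.0, abs=1e-12)
        assert brute_force_loss(jd.P, 0.0) == pytest.approx(0.0, abs=1e-12)

    def test_matches_brute_force_on_random_distributions(self, rng):
        for _ in range(100):
            shape = (int(rng.integers(2, 6)), int(rng.integers(2, 6)))
            p = rng.random(shape)
            p /= p.sum()
            alpha = float(rng.choice([0.0, 0.5, 1.0, 9.0]))
            vectorized = float(pair_contrastive_loss_t(Tensor(p), alpha).data)
            assert vectorized == pytest.approx(brute_force_loss(p, alpha), abs=1e-10)

    def test_alpha_zero_equals_negative_mutual_information(self, rng):
        """Independent cross-check: at alpha=0 the loss is minus the mutual
        information of the joint distribution, computed here via entropies
        (MI = H(row) + H(col) - H(joint))."""
        from scipy.stats import entropy

        for _ in range(10):
            p = rng.random((4, 5))
            p /= p.sum()
            mi = (
                entropy(p.sum(axis=1)) + entropy(p.sum(axis=0))
                - entropy(p.ravel())
            )
            loss = pair_contrastive_loss(JointDistribution(p), 0.0)
            assert loss == pytest.approx(-mi, abs=1e-10)

    def test_zero_entries_contribute_zero(self):
        p = np.array([[0.5, 0.0], [0.0, 0.5]])
        assert np.isfinite(pair_contrastive_loss(JointDistribution(p), 1.0))

    def test_symmetrized_loss_is_order_invariant(self, rng):
        si = random_stochastic(rng, 8, 5)
        sk = random_stochastic(rng, 8, 5)
        a = pair_contrastive_loss(joint_distribution(si, sk), 2.0)
        b = pair_contrastive_loss(joint_distribution(sk, si), 2.0)
        assert a == pytest.approx(b, abs=1e-10)


class TestMultiOmicsLoss:
    def test_two_identical_views_equal_twice_pair_loss(self, rng):
        z = rng.normal(size=(6, 4))
        bundle = make_bundle([z, z])
        total = float(multi_omics_contrastive_loss(bundle, alpha=1.0).data)
        s = latents_to_distributions(z)
        single = float(
            pair_contrastive_loss_t(
                Tensor(((s.data.T @ s.data) / 6 + (s.data.T @ s.data).T / 6) / 2
                       / ((s.data.T @ s.data) / 6).sum()),
                1.0,
            ).data
        )
        assert total == pytest.approx(2.0 * single, rel=1e-9)

    def test_three_views_have_six_ordered_terms(self, rng):
        """Relabeling symmetry + ordered-pair count: the total is twice the
        sum over the three unordered pairs."""
        zs = [rng.normal(size=(5, 3)) for _ in range(3)]
        bundle = make_bundle(zs)
        total = float(multi_omics_contrastive_loss(bundle, alpha=0.5).data)
        unordered = 0.0
        for i in range(3):
            for k in range(i + 1, 3):
                jd = joint_distribution(
                    latents_to_distributions(zs[i]).data,
                    latents_to_distributions(zs[k]).data,
                )
                unordered += pair_contrastive_loss(jd, 0.5)
        assert total == pytest.approx(2.0 * unordered, rel=1e-9)

    def test_unordered_convention_halves(self, rng):
        zs = [rng.normal(size=(5, 3)) for _ in range(2)]
        bundle = make_bundle(zs)
        ordered = float(multi_omics_contrastive_loss(bundle, 1.0, pairs="ordered").data)
        unordered = float(
            multi_omics_contrastive_loss(bundle, 1.0, pairs="unordered").data
        )
        assert ordered == pytest.approx(2.0 * unordered, rel=1e-12)

    def test_invariant_under_layer_relabeling(self, rng):
        zs = [rng.normal(size=(5, 3)) for _ in range(3)]
        a = float(multi_omics_contrastive_loss(make_bundle(zs), 1.0).data)
        b = float(
            multi_omics_contrastive_loss(make_bundle(zs[::-1]), 1.0).data
        )
        assert a == pytest.approx(b, rel=1e-10)

    def test_finite_for_extreme_latents(self, rng):
        zs = [rng.normal(size=(4, 3)) * 100 for _ in range(2)]
        total = float(multi_omics_contrastive_loss(make_bundle(zs), 9.0).data)
        assert np.isfinite(total)

    def test_alignment_improves_with_shared_signal(self, rng):
        """The mutual-information part (alpha=0 loss) should not increase as
        two views share more of their variance (marginal scale held fixed);
        checked by sign test over replicates."""
        wins = 0
        n_reps = 20
        for rep in range(n_reps):
            r = np.random.default_rng(rep)
            base = r.normal(size=(40, 6))
            losses = []
            for shared in (0.1, 0.9):
                w_shared, w_noise = np.sqrt(shared), np.sqrt(1 - shared)
                z1 = w_shared * base + w_noise * r.normal(size=base.shape)
                z2 = w_shared * base + w_noise * r.normal(size=base.shape)
                losses.append(
                    float(multi_omics_contrastive_loss(
                        make_bundle([z1, z2]), alpha=0.0).data)
                )
            if losses[1] <= losses[0]:
                wins += 1
        assert wins >= 0.7 * n_reps
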