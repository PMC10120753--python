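"""Loss components, composite objective, gradient sanity, training contract."""

import numpy as np
import pytest

from clclsa import (
    LossWeights,
    SyntheticSpec,
    TrainConfig,
    enumerate_grid,
    generate,
    grid_search,
    simulate_missingness,
    train,
)
from clclsa.attention import LatentBundle
from clclsa.nn import Linear, Sequential, Softmax, Tensor
from clclsa.objective import auxiliary_loss, classification_loss, total_loss

LN2 = float(np.log(2.0))


class TestClassificationLoss:
    def test_perfect_one_hot_is_zero(self):
        probs = np.eye(3)[[0, 1, 2]]
        labels = np.array([0, 1, 2])
        assert classification_loss(probs, labels).item() == pytest.approx(0.0)

    def test_half_confidence_gives_ln2(self):
        probs = np.full((4, 2), 0.5)
        labels = np.array([0, 1, 0, 1])
        assert classification_loss(probs, labels).item() == pytest.approx(LN2)

    @pytest.mark.parametrize("c", [2, 3, 5])
    def test_uniform_predictions_give_ln_c(self, c):
        probs = np.full((6, c), 1.0 / c)
        labels = np.arange(6) % c
        assert classification_loss(probs, labels).item() == pytest.approx(np.log(c))

    def test_zero_probability_is_clamped_finite(self):
        probs = np.array([[1.0, 0.0]])
        labels = np.array([1])
        loss = classification_loss(probs, labels).item()
        assert np.isfinite(loss) and loss > 20

    def test_label_out_of_range(self):
        with pytest.raises(ValueError, match="range"):
            classification_loss(np.full((2, 2), 0.5), np.array([0, 2]))


def _const_head(prob_rows):
    """A softmax head that always outputs the given probability rows."""
    class _Head:
        def __call__(self, z):
            n = z.shape[0]
            return Tensor(np.tile(prob_rows, (n, 1)))
    return _Head()


def _bundle_with_matt(matt_value, n=3, d=4, m=1):
    z = np.zeros((n, d))
    return LatentBundle(
        fatt=[Tensor(np.ones((n, d)))] * m,
        x_hat=[Tensor(z)] * m,
        matt=[Tensor(np.full((n, 1), matt_value))] * m,
        z_hat=[Tensor(z)] * m,
        defined=np.ones((n, m), dtype=bool),
    )


class TestAuxiliaryLoss:
    def test_matched_confidence_and_perfect_prediction_is_zero(self):
        bundle = _bundle_with_matt(1.0 - 1e-12)
        head = _const_head(np.array([[1.0, 0.0]]))
        labels = np.zeros(3, dtype=int)
        loss = auxiliary_loss(bundle, [head], labels).item()
        assert loss == pytest.approx(0.0, abs=1e-9)

    def test_half_confidence_binary_gives_ln2(self):
        """matt = confidence = 0.5 -> squared term 0; CE = ln 2."""
        bundle = _bundle_with_matt(0.5)
        head = _const_head(np.array([[0.5, 0.5]]))
        labels = np.zeros(3, dtype=int)
        assert auxiliary_loss(bundle, [head], labels).item() == pytest.approx(LN2)

    def test_confidence_gap_squared(self):
        """matt = 1, confidence = 0.5 -> squared term (1 - 0.5)^2 = 0.25."""
        bundle = _bundle_with_matt(1.0)
        head = _const_head(np.array([[0.5, 0.5]]))
        labels = np.zeros(3, dtype=int)
        assert auxiliary_loss(bundle, [head], labels).item() == pytest.approx(
            0.25 + LN2
        )

    def test_true_class_confidence_convention(self):
        bundle = _bundle_with_matt(0.8)
        head = _const_head(np.array([[0.2, 0.8]]))
        labels = np.zeros(3, dtype=int)  # true class prob = 0.2, max = 0.8
        loss_max = auxiliary_loss(bundle, [head], labels, confidence="max").item()
        loss_true = auxiliary_loss(
            bundle, [head], labels, confidence="true-class"
        ).item()
        assert loss_max == pytest.approx(-np.log(0.2))  # squared term 0
        assert loss_true == pytest.approx(0.6**2 - np.log(0.2))


class TestTotalLoss:
    def test_arithmetic_of_weighted_sum(self):
        total, breakdown = total_loss(
            Tensor(1.0), Tensor(2.0), Tensor(3.0), Tensor(-1.0),
            LossWeights(0.1, 1.0, 0.01),
        )
        assert total.item() == pytest.approx(1 + 0.2 + 3 - 0.01)
        assert breakdown.total == pytest.approx(4.19)

    def test_zero_weights_reduce_to_classification(self):
        total, breakdown = total_loss(
            Tensor(1.5), Tensor(9.0), Tensor(9.0), Tensor(9.0),
            LossWeights(0.0, 0.0, 0.0),
        )
        assert total.item() == pytest.approx(1.5)
        assert breakdown.clf == breakdown.total

    def test_breakdown_identity_holds(self, rng):
        w = LossWeights(0.05, 0.02, 1.0)
        vals = rng.normal(size=4)
        _, b = total_loss(*(Tensor(v) for v in vals), w)
        assert b.total == pytest.approx(
            b.clf + w.lam_al * b.al + w.lam_co * b.co + w.lam_cl * b.cl, abs=1e-8
        )

    def test_non_finite_component_is_named(self):
        with pytest.raises(FloatingPointError, match="co"):
            total_loss(Tensor(1.0), Tensor(1.0), Tensor(np.inf), Tensor(1.0),
                       LossWeights())

    def test_negative_weights_rejected(self):
        with pytest.raises(ValueError):
            LossWeights(-0.1, 0.0, 0.0)


class TestGrid:
    def test_incomplete_mode_has_180_cells(self):
        grid = enumerate_grid("incomplete")
        assert len(grid) == 180
        assert all(w.lam_co > 0 for w in grid)

    def test_complete_mode_has_36_cells(self):
        grid = enumerate_grid("complete")
        assert len(grid) == 36
        assert all(w.lam_co == 0 for w in grid)

    def test_singleton_grid_returns_that_config(self, tiny_dataset):
        cfg = TrainConfig(latent_dim=4, epochs=3, seed=0)
        only = LossWeights(0.1, 0.1, 0.01)
        best, table = grid_search(tiny_dataset, cfg, grid=[only])
        assert best == only and len(table) == 1


class TestTraining:
    def test_identical_seed_reproduces_losses(self, tiny_dataset):
        masked = simulate_missingness(tiny_dataset, 0.2, seed=1)
        cfg = TrainConfig(latent_dim=6, epochs=8, seed=3)
        a = train(masked, cfg)
        b = train(masked, cfg)
        assert abs(a.final_losses.total - b.final_losses.total) < 1e-6
        for ha, hb in zip(a.history, b.history):
            assert ha.as_dict() == hb.as_dict()

    def test_zero_weights_total_equals_classification(self, tiny_dataset):
        cfg = TrainConfig(latent_dim=6, epochs=5, seed=0, mode="complete",
                          lam_al=0.0, lam_cl=0.0)
        fitted = train(tiny_dataset, cfg)
        for h in fitted.history:
            assert h.total == pytest.approx(h.clf)
            assert h.al == 0.0 and h.co == 0.0 and h.cl == 0.0

    def test_all_incomplete_with_co_loss_raises(self, tiny_dataset):
        masked = simulate_missingness(tiny_dataset, 1.0, seed=0)
        cfg = TrainConfig(latent_dim=4, epochs=2, seed=0)
        with pytest.raises(ValueError, match="supervised"):
            train(masked, cfg)

    def test_complete_mode_forces_lam_co_zero(self):
        cfg = TrainConfig(mode="complete", lam_co=0.5)
        assert cfg.lam_co == 0.0

    def test_loss_decreases_on_easy_task(self, tiny_dataset):
        cfg = TrainConfig(latent_dim=6, epochs=150, lr=1e-3, seed=0,
                          mode="complete")
        fitted = train(tiny_dataset, cfg)
        assert fitted.history[-1].clf < 0.6 * fitted.history[0].clf


class TestGradientSanity:
    def test_each_component_matches_finite_differences(self, toy_dataset):
        """Central finite differences on one weight entry agree with the
        autodiff gradient to 1e-4 relative, per loss component."""
        from clclsa.model import CLCLSAModel, _epoch_losses

        masked = simulate_missingness(toy_dataset, 0.4, seed=0)
        cfg = TrainConfig(latent_dim=3, epochs=1, seed=1, dropout_p=0.0,
                          detach_imputed=False)
        weight_sets = {
            "clf": LossWeights(0.0, 0.0, 0.0),
            "al": LossWeights(1.0, 0.0, 0.0),
            "co": LossWeights(0.0, 1.0, 0.0),
            "cl": LossWeights(0.0, 0.0, 1.0),
        }
        for name, weights in weight_sets.items():
            model = CLCLSAModel(masked.feature_dims, masked.n_classes, cfg)
            # evaluation mode keeps the loss a pure function of the weights
            # (batch-norm running statistics are frozen), which central
            # finite differences require
            model.eval()
            param = model.encoders[0].emb.layers[0].weight
            total, _ = _epoch_losses(model, masked, weights)
            total.backward()
            autodiff = param.grad[0, 0]
            eps = 1e-6
            orig = param.data[0, 0]
            param.data[0, 0] = orig + eps
            hi, _ = _epoch_losses(model, masked, weights)
            param.data[0, 0] = orig - eps
            lo, _ = _epoch_losses(model, masked, weights)
            param.data[0, 0] = orig
            numeric = (hi.item() - lo.item()) / (2 * eps)
            assert autodiff == pytest.approx(numeric, rel=1e-4, abs=1e-8), name
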