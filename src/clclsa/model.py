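"""The full incomplete-multi-omics classifier and its training loop.

One model owns, per omics layer, the attention-gated encoder and an
auxiliary softmax head; across layers, the ``M * (M - 1)`` directed latent
translators; and one fused softmax classifier over the concatenated
latents. Training is full-batch: each epoch forwards every training
subject, supervises the translators on subjects observing both layers of
a pair, completes missing latents with the current translators (imputed
rows detached by default), and takes one Adam step on the composite
objective.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .attention import LatentBundle, OmicsEncoder, fuse
from .config import TrainConfig
from .contrastive import multi_omics_contrastive_loss
from .cross_omics import CrossOmicsTranslators, complete_missing, total_co_loss
from .data import MultiOmicsDataset
from .nn import Adam, Linear, Module, Sequential, Softmax, StepDecay, Tensor
from .objective import (
    LossBreakdown,
    LossWeights,
    auxiliary_loss,
    classification_loss,
    total_loss,
)

__all__ = ["CLCLSAModel", "TrainedModel", "train"]


class CLCLSAModel(Module):
    """Attention-gated encoders + latent translators + classifiers."""

    def __init__(
        self,
        feature_dims: tuple[int, ...],
        n_classes: int,
        config: TrainConfig,
    ):
        super().__init__()
        self.config = config
        self.feature_dims = tuple(feature_dims)
        self.n_classes = n_classes
        self.n_omics = len(feature_dims)
        rng = np.random.default_rng(config.seed)
        d = config.latent_dim
        self.encoders = [
            OmicsEncoder(
                v,
                d,
                rng,
                emb_arch=config.emb_arch,
                dropout_p=config.dropout_p,
                gated=config.attention == "gated",
                gate_convention=config.gate_convention,
            )
            for v in feature_dims
        ]
        self.translators = (
            CrossOmicsTranslators((d,) * self.n_omics, rng, arch=config.ae_arch)
            if self.n_omics >= 2
            else None
        )
        self.aux_heads = [
            Sequential(Linear(d, n_classes, rng), Softmax())
            for _ in feature_dims
        ]
        self.classifier = Sequential(
            Linear(d * self.n_omics, n_classes, rng), Softmax()
        )

    @property
    def fused_dim(self) -> int:
        return self.config.latent_dim * self.n_omics

    def _sanitize(self, dataset: MultiOmicsDataset) -> list[np.ndarray]:
        """Zero out rows of unobserved layers so stored placeholders (which
        may be anything finite, or NaN) never reach the network."""
        xs = []
        for i, layer in enumerate(dataset.layers):
            x = np.array(layer.values, dtype=np.float64)
            x[~dataset.mask.mask[:, i]] = 0.0
            xs.append(x)
        return xs

    def forward_bundle(self, dataset: MultiOmicsDataset) -> LatentBundle:
        """Per-layer attention outputs for every subject; latents of
        unobserved (subject, layer) pairs are zeroed and marked undefined."""
        xs = self._sanitize(dataset)
        mask = dataset.mask.mask
        fatt, x_hat, matt, z_hat = [], [], [], []
        for i, encoder in enumerate(self.encoders):
            fa, xh, ma, zh = encoder(xs[i])
            col = Tensor(mask[:, i : i + 1].astype(np.float64))
            z_hat.append(zh * col)
            x_hat.append(xh)
            fatt.append(fa)
            matt.append(ma)
        return LatentBundle(
            fatt=fatt, x_hat=x_hat, matt=matt, z_hat=z_hat, defined=mask.copy()
        )

    def completed_bundle(self, dataset: MultiOmicsDataset,
                         detach: bool | None = None) -> LatentBundle:
        bundle = self.forward_bundle(dataset)
        if bundle.defined.all():
            return LatentBundle(
                fatt=bundle.fatt, x_hat=bundle.x_hat, matt=bundle.matt,
                z_hat=bundle.z_hat, defined=np.ones_like(bundle.defined),
            )
        if self.translators is None:
            raise ValueError("single-layer model cannot complete missing omics")
        if detach is None:
            detach = self.config.detach_imputed
        return complete_missing(bundle, self.translators, dataset.mask, detach=detach)

    def predict_proba(self, dataset: MultiOmicsDataset) -> np.ndarray:
        """Class probabilities for every subject (evaluation mode)."""
        was_training = self.training
        self.eval()
        bundle = self.completed_bundle(dataset, detach=True)
        probs = self.classifier(fuse(bundle)).data
        if was_training:
            self.train()
        return probs

    def predict(self, dataset: MultiOmicsDataset) -> np.ndarray:
        return self.predict_proba(dataset).argmax(axis=1)


@dataclass
class TrainedModel:
    """A fitted model with its configuration and per-epoch history."""

    model: CLCLSAModel
    config: TrainConfig
    history: list[LossBreakdown] = field(default_factory=list)

    def predict_proba(self, dataset: MultiOmicsDataset) -> np.ndarray:
        return self.model.predict_proba(dataset)

    def predict(self, dataset: MultiOmicsDataset) -> np.ndarray:
        return self.model.predict(dataset)

    @property
    def final_losses(self) -> LossBreakdown:
        return self.history[-1]


def _epoch_losses(
    model: CLCLSAModel,
    dataset: MultiOmicsDataset,
    weights: LossWeights,
) -> tuple[Tensor, LossBreakdown]:
    config = model.config
    bundle = model.forward_bundle(dataset)
    if weights.lam_co > 0 and model.translators is not None:
        l_co = total_co_loss(
            bundle,
            model.translators,
            dataset.mask,
            form=config.co_form,
            supervision=config.co_supervision,
            subject_reduction="mean" if config.co_form == "mean" else "sum",
        )
    else:
        l_co = Tensor(0.0)
    if bundle.defined.all():
        completed = LatentBundle(
            fatt=bundle.fatt, x_hat=bundle.x_hat, matt=bundle.matt,
            z_hat=bundle.z_hat, defined=np.ones_like(bundle.defined),
        )
    else:
        completed = complete_missing(
            bundle, model.translators, dataset.mask, detach=config.detach_imputed
        )
    probs = model.classifier(fuse(completed))
    l_clf = classification_loss(probs, dataset.labels)
    if weights.lam_al > 0:
        l_al = auxiliary_loss(
            completed,
            model.aux_heads,
            dataset.labels,
            confidence=config.confidence,
            include_imputed=config.include_imputed_in_aux,
        )
    else:
        l_al = Tensor(0.0)
    if weights.lam_cl > 0 and model.n_omics >= 2:
        l_cl = multi_omics_contrastive_loss(completed, config.alpha, pairs=config.pairs)
    else:
        l_cl = Tensor(0.0)
    return total_loss(l_clf, l_al, l_co, l_cl, weights)


def train(
    dataset: MultiOmicsDataset,
    config: TrainConfig | None = None,
    weights: LossWeights | None = None,
) -> TrainedModel:
    """Fit the model on ``dataset`` with full-batch Adam.

    ``weights`` overrides the balance factors in ``config``. Deterministic
    given ``config.seed``. Raises when the reconstruction loss is active
    but no subject observes all layers (the translators would then have no
    complete-data supervision at all).
    """
    config = config or TrainConfig()
    if weights is None:
        weights = LossWeights(config.lam_al, config.lam_co, config.lam_cl)
    if config.mode == "complete":
        weights = LossWeights(weights.lam_al, 0.0, weights.lam_cl)
    if weights.lam_co > 0 and not dataset.mask.mask.all(axis=1).any():
        raise ValueError(
            "reconstruction loss is active but no subject has complete omics; "
            "the cross-omics autoencoders cannot be supervised"
        )
    model = CLCLSAModel(dataset.feature_dims, dataset.n_classes, config)
    model.train()
    optimizer = Adam(model.parameters(), lr=config.lr)
    schedule = StepDecay(optimizer, every=config.lr_decay_every,
                         factor=config.lr_decay_factor)
    history: list[LossBreakdown] = []
    for _ in range(config.epochs):
        total, breakdown = _epoch_losses(model, dataset, weights)
        optimizer.zero_grad()
        total.backward()
        optimizer.step()
        schedule.step()
        history.append(breakdown)
    model.eval()
    return TrainedModel(model=model, config=config, history=history)


# ---------------------------------------------------------------------------
# hyperparameter grid search


def enumerate_grid(
    mode: str = "incomplete",
    values: tuple[float, ...] | None = None,
) -> list[LossWeights]:
    """All balance-factor combinations for one training mode.

    Each weight ranges over {0, 0.01, 0.02, 0.05, 0.1, 1.0}; in complete
    mode the reconstruction weight is pinned at 0 (36 cells), in incomplete
    mode it must be positive (180 cells).
    """
    from .objective import GRID_VALUES

    values = values or GRID_VALUES
    if mode == "complete":
        co_values: tuple[float, ...] = (0.0,)
    elif mode == "incomplete":
        co_values = tuple(v for v in values if v > 0)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return [
        LossWeights(lam_al=al, lam_co=co, lam_cl=cl)
        for al in values
        for co in co_values
        for cl in values
    ]


def grid_search(
    dataset: MultiOmicsDataset,
    config: TrainConfig,
    grid: list[LossWeights] | None = None,
    val_fraction: float = 0.2,
):
    """Train every weight combination, select by validation accuracy.

    Ties are broken by lower final total loss, then by the lexicographically
    smallest (lam_al, lam_co, lam_cl). Returns ``(best_weights, table)``
    with one table row per combination.
    """
    import pandas as pd

    from .data import stratified_split

    if grid is None:
        grid = enumerate_grid(config.mode)
    if not grid:
        raise ValueError("the grid must be non-empty")
    split = stratified_split(dataset.labels, val_fraction, seed=config.seed)
    train_part = dataset.subset(split.train_indices)
    val_part = dataset.subset(split.test_indices)
    rows = []
    for weights in grid:
        fitted = train(train_part, config, weights=weights)
        probs = fitted.predict_proba(val_part)
        acc = float((probs.argmax(axis=1) == val_part.labels).mean())
        rows.append(
            {
                "lam_al": weights.lam_al,
                "lam_co": weights.lam_co,
                "lam_cl": weights.lam_cl,
                "val_acc": acc,
                "final_total_loss": fitted.final_losses.total,
            }
        )
    table = pd.DataFrame(rows)
    order = table.sort_values(
        by=["val_acc", "final_total_loss", "lam_al", "lam_co", "lam_cl"],
        ascending=[False, True, True, True, True],
        kind="mergesort",
    )
    best = order.iloc[0]
    best_weights = LossWeights(best["lam_al"], best["lam_co"], best["lam_cl"])
    return best_weights, table
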