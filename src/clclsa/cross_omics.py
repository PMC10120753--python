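"""Directed cross-omics latent autoencoders and missing-omics completion.

For every ordered pair of layers ``(i, k)`` with ``i != k`` a translator
``h_ik = dec_i o enc_k`` maps omics-``k`` latents into omics-``i`` latent
space, so a model with ``M`` layers carries ``M * (M - 1)`` translators.
They are supervised with the squared error between the translated latent
and the latent actually computed from observed omics-``i`` data, and at
inference time they fill in latents for unobserved layers — imputation
happens in latent space, never on raw features.
"""

from __future__ import annotations

import numpy as np

from .attention import LatentBundle
from .config import build_network, parse_architecture
from .data import PresenceMask
from .nn import Module, Tensor, as_tensor

__all__ = [
    "CrossOmicsTranslators",
    "pair_reconstruction_loss",
    "total_co_loss",
    "complete_missing",
]

DEFAULT_BOTTLENECK = "{d}-64-BN-ReLU-32-ReLU-64-BN-ReLU-{d}"


class CrossOmicsTranslators(Module):
    """The full set of directed translators ``h_ik`` for ``M`` layers.

    Parameters
    ----------
    latent_dims : D_i per layer (equal by construction, but kept general
        so translators between unequal widths still type-check).
    rng : generator for weight initialization.
    arch : optional architecture template; ``{d}`` placeholders are filled
        with source/target widths. The default is a bottlenecked stack with
        batch normalization and rectification.
    """

    def __init__(
        self,
        latent_dims: tuple[int, ...],
        rng: np.random.Generator,
        arch: str | None = None,
    ):
        super().__init__()
        self.latent_dims = tuple(latent_dims)
        m = len(latent_dims)
        self.nets: dict[tuple[int, int], Module] = {}
        self._net_list = []  # for Module.parameters discovery
        for i in range(m):
            for k in range(m):
                if i == k:
                    continue
                if arch is None:
                    text = DEFAULT_BOTTLENECK.format(d=latent_dims[k])
                    # retarget the final width to D_i
                    tokens = text.split("-")
                    tokens[-1] = str(latent_dims[i])
                    text = "-".join(tokens)
                else:
                    text = arch
                spec = parse_architecture(text)
                if spec.in_dim != latent_dims[k] or spec.out_dim != latent_dims[i]:
                    raise ValueError(
                        f"translator architecture {text!r} does not map "
                        f"D_{k}={latent_dims[k]} -> D_{i}={latent_dims[i]}"
                    )
                net = build_network(spec, rng)
                self.nets[(i, k)] = net
                self._net_list.append(net)

    @property
    def n_translators(self) -> int:
        return len(self.nets)

    def predict_latent(self, i: int, k: int, z_k) -> Tensor:
        """Translate omics-``k`` latents into omics-``i`` latent space."""
        if i == k:
            raise ValueError(f"invalid translator pair ({i}, {k}): i must differ from k")
        z_k = as_tensor(z_k)
        if z_k.shape[-1] != self.latent_dims[k]:
            raise ValueError(
                f"latent width {z_k.shape[-1]} != D_{k}={self.latent_dims[k]}"
            )
        return self.nets[(i, k)](z_k)


def pair_reconstruction_loss(predicted, target, form: str = "sum") -> Tensor:
    """Squared error between a translated latent and its target.

    ``form="sum"`` is the printed squared Euclidean norm; ``form="mean"``
    averages over latent dimensions, which keeps the loss scale independent
    of D and is the trainer's internal default.
    """
    predicted, target = as_tensor(predicted), as_tensor(target)
    if predicted.shape != target.shape:
        raise ValueError(f"shape mismatch {predicted.shape} vs {target.shape}")
    sq = (predicted - target) ** 2
    if form == "sum":
        return sq.sum()
    if form == "mean":
        return sq.mean()
    raise ValueError(f"unknown form {form!r}")


def total_co_loss(
    bundle: LatentBundle,
    translators: CrossOmicsTranslators,
    mask: PresenceMask,
    form: str = "sum",
    supervision: str = "pairwise",
    subject_reduction: str = "sum",
) -> Tensor:
    """Cross-omics reconstruction loss over all ordered layer pairs.

    A subject supervises translator ``h_ik`` only when layers ``i`` and
    ``k`` are both observed (``supervision="pairwise"``); with
    ``supervision="complete-only"`` only fully observed subjects
    contribute, the stricter historical rule. ``subject_reduction="mean"``
    divides by the number of supervised subject-pair terms.
    """
    m = bundle.n_layers
    total = Tensor(0.0)
    n_terms = 0
    for i in range(m):
        for k in range(m):
            if i == k:
                continue
            if supervision == "pairwise":
                rows = mask.observed_pairs(i, k)
            elif supervision == "complete-only":
                rows = mask.mask.all(axis=1)
            else:
                raise ValueError(f"unknown supervision {supervision!r}")
            if not rows.any():
                continue
            idx = np.flatnonzero(rows)
            pred = translators.predict_latent(i, k, bundle.z_hat[k][idx])
            diff = (pred - bundle.z_hat[i][idx]) ** 2
            per_subject = diff.sum(axis=1) if form == "sum" else diff.mean(axis=1)
            total = total + per_subject.sum()
            n_terms += idx.size
    if subject_reduction == "mean" and n_terms > 0:
        total = total / float(n_terms)
    return total


def complete_missing(
    bundle: LatentBundle,
    translators: CrossOmicsTranslators,
    mask: PresenceMask,
    detach: bool = True,
) -> LatentBundle:
    """Fill in latents for unobserved layers.

    For a missing (subject, layer-``i``) entry the imputed latent is the
    unweighted mean of ``h_ik(z_hat_k)`` over the subject's observed source
    layers ``k``. Observed entries are untouched. With ``detach=True`` the
    imputed rows are constants for downstream consumers, so the classifier
    path does not push gradients through the translators being trained.
    """
    observed = mask.mask
    if not observed.any(axis=1).all():
        bad = int(np.flatnonzero(~observed.any(axis=1))[0])
        raise ValueError(f"subject {bad} observes no layers; cannot complete")
    # completion always applies the translators as trained maps: batch-norm
    # layers use running statistics, independent of how few rows are missing
    was_training = translators.training
    translators.eval()
    m = bundle.n_layers
    n = observed.shape[0]
    new_z: list[Tensor] = []
    imputed = bundle.imputed.copy()
    for i in range(m):
        missing_rows = np.flatnonzero(~observed[:, i])
        if missing_rows.size == 0:
            new_z.append(bundle.z_hat[i])
            continue
        # translate from every possible source, then average the ones
        # actually observed per subject
        acc_t: Tensor | None = None
        counts = np.zeros((missing_rows.size, 1))
        for k in range(m):
            if k == i:
                continue
            src_rows = missing_rows[observed[missing_rows, k]]
            if src_rows.size == 0:
                continue
            pred = translators.predict_latent(i, k, bundle.z_hat[k][src_rows])
            sel = np.isin(missing_rows, src_rows)
            weight = np.zeros((missing_rows.size, src_rows.size))
            weight[np.flatnonzero(sel), np.arange(src_rows.size)] = 1.0
            contribution = Tensor(weight) @ pred if not detach else Tensor(
                weight @ pred.data
            )
            acc_t = contribution if acc_t is None else acc_t + contribution
            counts[sel] += 1
        mean_imputed = acc_t * Tensor(1.0 / counts)
        # scatter imputed rows back into the full latent matrix without
        # touching observed rows
        keep = np.ones((n, 1))
        keep[missing_rows] = 0.0
        scatter = np.zeros((n, missing_rows.size))
        scatter[missing_rows, np.arange(missing_rows.size)] = 1.0
        full = bundle.z_hat[i] * Tensor(keep) + Tensor(scatter) @ mean_imputed
        new_z.append(full)
        imputed[missing_rows, i] = True
    if was_training:
        translators.train()
    return LatentBundle(
        fatt=bundle.fatt,
        x_hat=bundle.x_hat,
        matt=bundle.matt,
        z_hat=new_z,
        defined=np.ones_like(bundle.defined),
        imputed=imputed,
    )
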