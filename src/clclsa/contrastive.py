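"""Cross-view contrastive objective over latent-dimension distributions.

Latent matrices are mapped row-wise through a softmax so each subject
contributes a probability distribution over latent dimensions; averaging
the outer products of paired per-subject distributions gives a joint
probability matrix ``P`` over the latent dimensions of two omics layers.
The loss

    L = - sum_{d,d'} P_{dd'} * ln( P_{dd'} / (P_d^{a+1} * P_{d'}^{a+1}) )

decomposes into minus the mutual information between the two views'
latent-dimension variables plus ``alpha`` times their marginal entropies:
minimizing it aligns the views while the entropy term keeps individual
latent dimensions from collapsing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .attention import LatentBundle
from .nn import Tensor, as_tensor

__all__ = [
    "JointDistribution",
    "latents_to_distributions",
    "joint_distribution",
    "pair_contrastive_loss",
    "pair_contrastive_loss_t",
    "multi_omics_contrastive_loss",
]

_FLOOR = 1e-12  # clamp inside logarithms; 0 * ln 0 := 0


@dataclass
class JointDistribution:
    """A D_i x D_k joint probability matrix with its marginals."""

    P: np.ndarray
    alpha: float = 0.0

    def __post_init__(self) -> None:
        self.P = np.asarray(self.P, dtype=np.float64)
        if (self.P < 0).any():
            raise ValueError("joint distribution entries must be non-negative")
        if abs(self.P.sum() - 1.0) > 1e-9:
            raise ValueError("joint distribution must sum to 1")

    @property
    def row_marginals(self) -> np.ndarray:
        return self.P.sum(axis=1)

    @property
    def col_marginals(self) -> np.ndarray:
        return self.P.sum(axis=0)


def latents_to_distributions(z) -> Tensor:
    """Row-wise softmax: each subject's latent becomes a distribution over
    latent dimensions (shift-invariant, entries in (0, 1), rows sum to 1)."""
    return as_tensor(z).softmax(axis=-1)


def _joint_t(s_i: Tensor, s_k: Tensor, symmetrize: bool = True) -> Tensor:
    """Joint probability matrix as a Tensor (differentiable path)."""
    if s_i.shape[0] != s_k.shape[0]:
        raise ValueError(
            f"paired views need equal subject counts, got {s_i.shape[0]} vs {s_k.shape[0]}"
        )
    n = s_i.shape[0]
    p = (s_i.T @ s_k) / float(n)
    if symmetrize and p.shape[0] == p.shape[1]:
        p = (p + p.T) * 0.5
    return p / p.sum()


def joint_distribution(s_i, s_k, alpha: float = 0.0,
                       symmetrize: bool = True) -> JointDistribution:
    """Build the joint distribution of two row-stochastic N x D matrices.

    ``P = (1/N) sum_j outer(s_i[j], s_k[j])``, symmetrized and renormalized
    when square so the pair loss is order-independent.
    """
    p = _joint_t(as_tensor(np.asarray(s_i)), as_tensor(np.asarray(s_k)),
                 symmetrize=symmetrize)
    return JointDistribution(P=p.data, alpha=alpha)


def pair_contrastive_loss_t(p: Tensor, alpha: float) -> Tensor:
    """Differentiable contrastive loss of a joint probability Tensor."""
    row = p.sum(axis=1, keepdims=True)
    col = p.sum(axis=0, keepdims=True)
    log_ratio = (
        p.clamp_min(_FLOOR).log()
        - (alpha + 1.0) * row.clamp_min(_FLOOR).log()
        - (alpha + 1.0) * col.clamp_min(_FLOOR).log()
    )
    return -(p * log_ratio).sum()


def pair_contrastive_loss(joint: JointDistribution, alpha: float | None = None) -> float:
    """Contrastive loss of a joint distribution (scalar convenience form)."""
    if alpha is None:
        alpha = joint.alpha
    return float(pair_contrastive_loss_t(Tensor(joint.P), alpha).data)


def multi_omics_contrastive_loss(
    bundle: LatentBundle, alpha: float, pairs: str = "ordered"
) -> Tensor:
    """Sum of pair losses over layer pairs of a (completed) latent bundle.

    ``pairs="ordered"`` follows the printed double sum with the ``i != k``
    indicator (each unordered pair counted twice); ``pairs="unordered"``
    halves it.
    """
    m = bundle.n_layers
    if m < 2:
        raise ValueError("contrastive loss needs at least two omics layers")
    dists = [latents_to_distributions(z) for z in bundle.z_hat]
    total = Tensor(0.0)
    for i in range(m):
        for k in range(i + 1, m):
            p_ik = _joint_t(dists[i], dists[k])
            loss = pair_contrastive_loss_t(p_ik, alpha)
            if pairs == "ordered":
                # with symmetrized P the (k, i) term equals the (i, k) term
                total = total + loss * 2.0
            elif pairs == "unordered":
                total = total + loss
            else:
                raise ValueError(f"unknown pair convention {pairs!r}")
    return total
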