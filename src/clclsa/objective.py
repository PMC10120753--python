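"""Classification, auxiliary-confidence and composite losses.

The composite objective is

    L = L_clf + lam_al * L_al + lam_co * L_co + lam_cl * L_cl

where ``L_clf`` is the cross-entropy of the fused classifier, ``L_al``
ties each omics-level attention score to its auxiliary classifier's
confidence (squared difference) and adds the auxiliary cross-entropy,
``L_co`` is the cross-omics reconstruction loss and ``L_cl`` the
cross-view contrastive loss. All four components are reported separately
at every step.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .attention import LatentBundle
from .nn import Module, Tensor, as_tensor

__all__ = [
    "GRID_VALUES",
    "LossWeights",
    "LossBreakdown",
    "classification_loss",
    "auxiliary_loss",
    "total_loss",
]

GRID_VALUES: tuple[float, ...] = (0.0, 0.01, 0.02, 0.05, 0.1, 1.0)

_PROB_FLOOR = 1e-12


@dataclass(frozen=True)
class LossWeights:
    """Non-negative balance factors for the three regularizing losses."""

    lam_al: float = 0.1
    lam_co: float = 0.1
    lam_cl: float = 0.01

    def __post_init__(self) -> None:
        if min(self.lam_al, self.lam_co, self.lam_cl) < 0:
            raise ValueError("loss weights must be non-negative")

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.lam_al, self.lam_co, self.lam_cl)


@dataclass
class LossBreakdown:
    """The four components and their weighted total for one step."""

    clf: float
    al: float
    co: float
    cl: float
    total: float

    def as_dict(self) -> dict[str, float]:
        return {"clf": self.clf, "al": self.al, "co": self.co,
                "cl": self.cl, "total": self.total}


def classification_loss(probs, labels) -> Tensor:
    """Mean negative log-probability of the true class.

    ``probs`` rows must lie on the simplex; probabilities are clamped at
    1e-12 inside the logarithm so a confidently wrong prediction yields a
    large finite penalty.
    """
    probs = as_tensor(probs)
    labels = np.asarray(labels, dtype=np.int64)
    n = probs.shape[0]
    if labels.shape != (n,):
        raise ValueError(f"{labels.shape[0]} labels for {n} probability rows")
    if labels.min() < 0 or labels.max() >= probs.shape[1]:
        raise ValueError("labels outside the classifier's class range")
    p_true = probs[np.arange(n), labels]
    return -(p_true.clamp_min(_PROB_FLOOR).log().mean())


def auxiliary_loss(
    bundle: LatentBundle,
    aux_heads: list[Module],
    labels,
    confidence: str = "max",
    include_imputed: bool = True,
) -> Tensor:
    """Confidence-regularized auxiliary classification loss.

    Per omics layer: the squared difference between the omics attention
    score and the auxiliary classifier's confidence (its maximal softmax
    output by default, the true-class probability with
    ``confidence="true-class"``), plus the auxiliary cross-entropy. Both
    parts are averaged over the batch and summed over layers. The squared
    term is only defined where the layer was actually observed (attention
    scores exist only for real inputs); the cross-entropy term covers
    imputed entries too unless ``include_imputed=False``.
    """
    labels = np.asarray(labels, dtype=np.int64)
    total = Tensor(0.0)
    observed = bundle.defined & ~bundle.imputed
    for i, head in enumerate(aux_heads):
        probs = head(bundle.z_hat[i])
        rows = observed[:, i] | (bundle.imputed[:, i] if include_imputed else False)
        ce_rows = np.flatnonzero(rows)
        if ce_rows.size:
            p_true = probs[ce_rows, labels[ce_rows]]
            total = total - p_true.clamp_min(_PROB_FLOOR).log().mean()
        obs_rows = np.flatnonzero(observed[:, i])
        if obs_rows.size:
            if confidence == "max":
                conf = probs[obs_rows].max(axis=1)
            elif confidence == "true-class":
                conf = probs[obs_rows, labels[obs_rows]]
            else:
                raise ValueError(f"unknown confidence convention {confidence!r}")
            matt = bundle.matt[i][obs_rows].reshape(-1)
            total = total + ((matt - conf) ** 2).mean()
    return total


def total_loss(
    l_clf: Tensor,
    l_al: Tensor,
    l_co: Tensor,
    l_cl: Tensor,
    weights: LossWeights,
) -> tuple[Tensor, LossBreakdown]:
    """Weighted sum of the four components; also returns the scalar report.

    Raises on any non-finite component, naming it.
    """
    components = {"clf": l_clf, "al": l_al, "co": l_co, "cl": l_cl}
    for name, value in components.items():
        if not np.isfinite(value.data).all():
            raise FloatingPointError(f"loss component {name!r} is non-finite")
    total = (
        l_clf
        + weights.lam_al * l_al
        + weights.lam_co * l_co
        + weights.lam_cl * l_cl
    )
    breakdown = LossBreakdown(
        clf=float(l_clf.data),
        al=float(l_al.data),
        co=float(l_co.data),
        cl=float(l_cl.data),
        total=float(total.data),
    )
    return total, breakdown
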