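"""Self-attention gating and fusion of omics-specific embeddings.

Each omics layer gets three small networks: a feature-level gate ``f_i``
(sigmoid over a linear map of the raw features), an embedding network
``emb_i`` (linear, rectified, dropout-regularized), and an omics-level gate
``g_i`` producing one sigmoid scalar per subject interpreted as the layer's
confidence. The gated, embedded latents are concatenated across layers into
the representation the classifier consumes.

The printed form of the feature gate multiplies the embedding output by a
gate of input width, which is ill-typed whenever the embedding changes
dimension; the default convention here gates the *input* features,
``x_hat = emb_i(x * fatt)``, with the post-embedding alternative available
via ``gate_convention="output"`` (only valid when the embedding preserves
width).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .config import build_network, parse_architecture
from .nn import Linear, Module, Sequential, Tensor, as_tensor, cat

__all__ = [
    "OmicsEncoder",
    "LatentBundle",
    "feature_attention",
    "embed_with_feature_attention",
    "omics_attention",
    "scale_by_omics_attention",
    "fuse",
]


def feature_attention(x, f: Module) -> Tensor:
    """Feature-level gate: elementwise sigmoid of a linear map of ``x``.

    Returns values strictly inside (0, 1), one per input feature.
    """
    return f(as_tensor(x)).sigmoid()


def embed_with_feature_attention(
    x, fatt, emb: Module, convention: str = "input"
) -> Tensor:
    """Embed ``x`` with the feature gate applied.

    ``convention="input"`` computes ``emb(x * fatt)`` (gates select input
    features before embedding); ``convention="output"`` computes
    ``emb(x) * fatt`` and requires the gate width to match the embedding
    output width.
    """
    x, fatt = as_tensor(x), as_tensor(fatt)
    if convention == "input":
        if x.shape[-1] != fatt.shape[-1]:
            raise ValueError(
                f"gate width {fatt.shape[-1]} != feature width {x.shape[-1]}"
            )
        return emb(x * fatt)
    if convention == "output":
        out = emb(x)
        if out.shape[-1] != fatt.shape[-1]:
            raise ValueError(
                f"gate width {fatt.shape[-1]} != embedding width {out.shape[-1]}"
            )
        return out * fatt
    raise ValueError(f"unknown gate convention {convention!r}")


def omics_attention(x_hat, g: Module) -> Tensor:
    """Omics-level gate: one sigmoid scalar per subject from the embedded
    latent, interpreted as the modality's importance/confidence."""
    return g(as_tensor(x_hat)).sigmoid()


def scale_by_omics_attention(x_hat, matt) -> Tensor:
    """Scale the whole latent vector by its omics-level gate (broadcast)."""
    return as_tensor(x_hat) * as_tensor(matt)


class OmicsEncoder(Module):
    """The per-omics stack: feature gate, embedding, omics gate.

    Parameters
    ----------
    in_dim : raw feature width V_i.
    latent_dim : embedding width D_i (equal across layers by construction).
    rng : generator for weight initialization and dropout masks.
    emb_arch : optional architecture string for the embedding network;
        defaults to ``"{V}-{D}-ReLU-DP"``.
    gated : with ``False`` both gates are bypassed as identity (the "plain"
        ablation variant).
    """

    def __init__(
        self,
        in_dim: int,
        latent_dim: int,
        rng: np.random.Generator,
        emb_arch: str | None = None,
        dropout_p: float = 0.5,
        gated: bool = True,
        gate_convention: str = "input",
    ):
        super().__init__()
        self.in_dim = in_dim
        self.latent_dim = latent_dim
        self.gated = gated
        self.gate_convention = gate_convention
        self.f = Linear(in_dim, in_dim, rng)
        arch = emb_arch or f"{in_dim}-{latent_dim}-ReLU-DP"
        spec = parse_architecture(arch)
        if spec.in_dim != in_dim or spec.out_dim != latent_dim:
            raise ValueError(
                f"embedding architecture {arch!r} does not map {in_dim} -> {latent_dim}"
            )
        self.emb: Sequential = build_network(spec, rng, dropout_p=dropout_p)
        self.g = Linear(latent_dim, 1, rng)

    def forward(self, x) -> tuple[Tensor, Tensor, Tensor, Tensor]:
        """Return ``(fatt, x_hat, matt, z_hat)`` for a batch of subjects."""
        x = as_tensor(x)
        if not self.gated:
            x_hat = self.emb(x)
            ones = Tensor(np.ones((x.shape[0], 1)))
            return (
                Tensor(np.ones_like(x.data)),
                x_hat,
                ones,
                x_hat,
            )
        fatt = feature_attention(x, self.f)
        x_hat = embed_with_feature_attention(x, fatt, self.emb, self.gate_convention)
        matt = omics_attention(x_hat, self.g)
        z_hat = scale_by_omics_attention(x_hat, matt)
        return fatt, x_hat, matt, z_hat


@dataclass
class LatentBundle:
    """Per-layer batched attention outputs plus provenance.

    ``z_hat[i]`` is the N x D latent of layer ``i``; rows whose layer is
    unobserved are only meaningful after completion, at which point
    ``imputed[:, i]`` flags them. ``defined`` records for which (subject,
    layer) pairs ``z_hat`` is currently valid.
    """

    fatt: list[Tensor]
    x_hat: list[Tensor]
    matt: list[Tensor]
    z_hat: list[Tensor]
    defined: np.ndarray  # N x M bool
    imputed: np.ndarray = field(default=None)  # N x M bool

    def __post_init__(self) -> None:
        if self.imputed is None:
            self.imputed = np.zeros_like(self.defined)

    @property
    def n_layers(self) -> int:
        return len(self.z_hat)

    @property
    def latent_dims(self) -> tuple[int, ...]:
        return tuple(z.shape[1] for z in self.z_hat)


def fuse(bundle: LatentBundle) -> Tensor:
    """Concatenate per-layer latents into the N x (sum D_i) representation.

    Every (subject, layer) latent must be defined (observed or imputed);
    otherwise completion is still required and an error is raised.
    """
    if not bundle.defined.all():
        j, i = np.argwhere(~bundle.defined)[0]
        raise ValueError(
            f"latent for subject {j}, layer {i} is undefined; "
            "run completion before fusing"
        )
    return cat(bundle.z_hat, axis=1)
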