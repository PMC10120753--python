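"""Architecture-string grammar and run configuration.

Network shapes are written in a compact dialect, e.g. ``"2000-200-ReLU-DP"``
or ``"300-64-BN-ReLU-32-ReLU-64-BN-ReLU-300"``: integers are the widths of
successive linear maps, and ``BN`` (batch normalization), ``ReLU``, ``DP``
(dropout) and ``Softmax`` modify the stage introduced by the preceding pair
of widths.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Any

import numpy as np
import yaml

from .nn import BatchNorm1d, Dropout, Linear, ReLU, Sequential, Softmax

__all__ = [
    "ArchitectureSpec",
    "parse_architecture",
    "build_network",
    "TrainConfig",
    "load_train_config",
]

_MODIFIERS = {"ReLU", "BN", "DP", "Softmax"}


@dataclass(frozen=True)
class ArchitectureSpec:
    """Parsed layer stack: the token list plus input/output widths."""

    tokens: tuple[str, ...]
    dims: tuple[int, ...]

    @property
    def in_dim(self) -> int:
        return self.dims[0]

    @property
    def out_dim(self) -> int:
        return self.dims[-1]

    def __str__(self) -> str:
        return "-".join(self.tokens)


def parse_architecture(text: str) -> ArchitectureSpec:
    """Parse an architecture string, validating every token.

    Raises ``ValueError`` naming the position of the first unknown token.
    """
    tokens = [t.strip() for t in text.strip().split("-")]
    dims: list[int] = []
    for pos, token in enumerate(tokens, start=1):
        if token.isdigit():
            dims.append(int(token))
            if dims[-1] <= 0:
                raise ValueError(f"token {pos} ({token!r}): layer width must be positive")
        elif token in _MODIFIERS:
            if not dims:
                raise ValueError(f"token {pos} ({token!r}): modifier before any width")
        else:
            raise ValueError(f"token {pos} ({token!r}): unknown token in {text!r}")
    if len(dims) < 2:
        raise ValueError(f"architecture {text!r} needs at least two widths")
    return ArchitectureSpec(tokens=tuple(tokens), dims=tuple(dims))


def build_network(arch: ArchitectureSpec | str, rng: np.random.Generator,
                  dropout_p: float = 0.5) -> Sequential:
    """Instantiate the layer stack an architecture string describes."""
    if isinstance(arch, str):
        arch = parse_architecture(arch)
    layers = []
    current_dim: int | None = None
    for token in arch.tokens:
        if token.isdigit():
            width = int(token)
            if current_dim is not None:
                layers.append(Linear(current_dim, width, rng))
            current_dim = width
        elif token == "ReLU":
            layers.append(ReLU())
        elif token == "BN":
            layers.append(BatchNorm1d(current_dim))
        elif token == "DP":
            layers.append(Dropout(dropout_p, rng=np.random.default_rng(rng.integers(2**31))))
        elif token == "Softmax":
            layers.append(Softmax())
    return Sequential(*layers)


@dataclass
class TrainConfig:
    """Everything one training run needs besides the dataset itself.

    Defaults follow the reference training recipe: Adam at learning rate
    1e-4 with step decay x0.2 every 500 epochs, full-batch updates, dropout
    probability 0.5, and the entropy weight ``alpha`` of the contrastive
    loss at 9.0.
    """

    latent_dim: int = 32
    epochs: int = 300
    lr: float = 1e-4
    lr_decay_every: int = 500
    lr_decay_factor: float = 0.2
    lam_al: float = 0.1
    lam_co: float = 0.1
    lam_cl: float = 0.01
    alpha: float = 9.0
    dropout_p: float = 0.5
    seed: int = 0
    mode: str = "incomplete"  # "complete" forces lam_co to 0
    co_form: str = "mean"  # "sum" reproduces the printed squared-norm form
    co_supervision: str = "pairwise"  # or "complete-only"
    pairs: str = "ordered"  # contrastive pair convention; "unordered" halves
    attention: str = "gated"  # "identity" bypasses both attention gates
    gate_convention: str = "input"  # or "output" (post-embedding gating)
    detach_imputed: bool = True
    include_imputed_in_aux: bool = True
    confidence: str = "max"  # or "true-class"
    emb_arch: str | None = None  # per-layer override, e.g. "200-300-ReLU-DP"
    ae_arch: str | None = None  # e.g. "300-64-BN-ReLU-32-ReLU-64-BN-ReLU-300"

    def __post_init__(self) -> None:
        if self.mode not in ("complete", "incomplete"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.mode == "complete":
            self.lam_co = 0.0
        if min(self.lam_al, self.lam_co, self.lam_cl) < 0:
            raise ValueError("loss weights must be non-negative")

    def replace(self, **kwargs: Any) -> "TrainConfig":
        data = {**self.__dict__, **kwargs}
        return TrainConfig(**data)


def load_train_config(path: str | Path) -> TrainConfig:
    """Read a YAML mapping of TrainConfig fields."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    known = set(TrainConfig.__dataclass_fields__)
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return TrainConfig(**raw)
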