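"""Synthetic multi-omics generator with known shared-factor structure.

All layers are noisy linear views of one class-dependent latent factor:
for subject ``j`` with class ``y``, the shared latent is
``s ~ Normal(mu_y, I_d)`` with class means placed at the vertices of a
regular simplex at mutual distance ``class_separation``; layer ``i`` is
``X_i[j] = s W_i + eps`` with a fixed random loading matrix ``W_i`` of
shape ``d_shared x V_i`` and isotropic Gaussian noise of standard
deviation ``noise_sd``. This linear-Gaussian design keeps every downstream
claim checkable: any two layers are deterministic functions of the same
latent up to noise, so cross-omics translation has an analytic target and
class separability is controlled by ``class_separation / noise_sd``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .data import MultiOmicsDataset, OmicsLayer, PresenceMask

__all__ = ["SyntheticSpec", "GroundTruth", "simplex_vertices", "generate"]


@dataclass(frozen=True)
class SyntheticSpec:
    """Generator settings; defaults give a moderately hard 3-layer binary task."""

    n_subjects: int = 200
    n_layers: int = 3
    n_classes: int = 2
    feature_dims: tuple[int, ...] = (50, 50, 30)
    d_shared: int = 5
    class_separation: float = 4.0
    noise_sd: float | tuple[float, ...] = 1.0
    signal_fraction: float = 1.0
    corrupt_fraction: float = 0.0
    corrupt_scale: float = 5.0
    loading_seed: int = 7
    sample_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < self.n_classes:
            raise ValueError("need at least one subject per class")
        if self.n_layers != len(self.feature_dims):
            raise ValueError("feature_dims must have one entry per layer")
        if self.d_shared < 1 or min(self.feature_dims) < 1:
            raise ValueError("all dimensions must be positive")
        if self.d_shared < self.n_classes - 1:
            raise ValueError("d_shared must be >= n_classes - 1 to place the simplex")
        if self.class_separation < 0:
            raise ValueError("class_separation must be non-negative")
        if min(self.noise_levels) <= 0:
            raise ValueError("noise_sd must be positive")
        if len(self.noise_levels) != self.n_layers:
            raise ValueError("per-layer noise_sd needs one entry per layer")
        if not 0.0 < self.signal_fraction <= 1.0:
            raise ValueError("signal_fraction must be in (0, 1]")
        if not 0.0 <= self.corrupt_fraction <= 1.0:
            raise ValueError("corrupt_fraction must be in [0, 1]")
        if self.corrupt_scale < 1.0:
            raise ValueError("corrupt_scale must be >= 1")

    @property
    def noise_levels(self) -> tuple[float, ...]:
        """Per-layer noise standard deviations (scalar broadcast to all)."""
        if isinstance(self.noise_sd, (int, float)):
            return (float(self.noise_sd),) * self.n_layers
        return tuple(float(v) for v in self.noise_sd)


@dataclass
class GroundTruth:
    """What the generator knows and the model must recover."""

    shared_latents: np.ndarray  # N x d_shared
    class_means: np.ndarray  # C x d_shared
    loadings: list[np.ndarray] = field(default_factory=list)  # d_shared x V_i


def simplex_vertices(n_classes: int, dim: int, separation: float) -> np.ndarray:
    """``n_classes`` points in ``R^dim`` with all pairwise distances equal to
    ``separation``, centered at the origin."""
    if dim < n_classes - 1:
        raise ValueError("dim must be >= n_classes - 1")
    # vertices of the regular simplex from the standard basis of R^C,
    # projected onto their affine span and padded to `dim`
    basis = np.eye(n_classes)
    centered = basis - basis.mean(axis=0)
    # orthonormal basis for the span via QR on the centered vertices
    q, _ = np.linalg.qr(centered.T)
    coords = centered @ q[:, : n_classes - 1]
    if n_classes > 1:
        coords *= separation / np.sqrt(2.0)  # basis vertices are sqrt(2) apart
    out = np.zeros((n_classes, dim))
    out[:, : n_classes - 1] = coords
    return out


def generate(spec: SyntheticSpec) -> tuple[MultiOmicsDataset, GroundTruth]:
    """Draw one dataset. Labels are balanced up to remainder and shuffled;
    the returned mask is all-true (apply ``simulate_missingness`` for
    incomplete designs). Bit-reproducible given the two seeds."""
    load_rng = np.random.default_rng(spec.loading_seed)
    sample_rng = np.random.default_rng(spec.sample_seed)

    means = simplex_vertices(spec.n_classes, spec.d_shared, spec.class_separation)
    loadings = []
    for v in spec.feature_dims:
        w = load_rng.standard_normal((spec.d_shared, v)) / np.sqrt(spec.d_shared)
        if spec.signal_fraction < 1.0:
            # sparse loadings: only a fraction of features carry the shared
            # factor, the rest are pure noise (few-differential-features regime)
            n_signal = max(1, int(round(spec.signal_fraction * v)))
            silent = load_rng.choice(v, size=v - n_signal, replace=False)
            w[:, silent] = 0.0
        loadings.append(w)

    labels = np.arange(spec.n_subjects) % spec.n_classes
    labels = sample_rng.permutation(labels)
    latents = means[labels] + sample_rng.standard_normal(
        (spec.n_subjects, spec.d_shared)
    )
    layers = []
    for i, (v, w, sd) in enumerate(
        zip(spec.feature_dims, loadings, spec.noise_levels)
    ):
        noise = sd * sample_rng.standard_normal((spec.n_subjects, v))
        values = latents @ w + noise
        if spec.corrupt_fraction > 0:
            # per-subject quality variation: a random subset of this layer's
            # measurements are replaced by pure high-variance noise (degraded
            # samples/failed assays), so modality reliability varies per
            # subject rather than per layer
            n_bad = int(round(spec.corrupt_fraction * spec.n_subjects))
            bad = sample_rng.choice(spec.n_subjects, size=n_bad, replace=False)
            values[bad] = spec.corrupt_scale * sd * sample_rng.standard_normal(
                (n_bad, v)
            )
        layers.append(OmicsLayer(f"omics{i + 1}", values))

    dataset = MultiOmicsDataset(
        layers=layers,
        mask=PresenceMask(np.ones((spec.n_subjects, spec.n_layers), dtype=bool)),
        labels=labels,
        n_classes=spec.n_classes,
        meta={
            "generator": "shared-factor linear-Gaussian",
            "class_separation": spec.class_separation,
            "noise_sd": list(spec.noise_levels),
            "loading_seed": spec.loading_seed,
            "sample_seed": spec.sample_seed,
        },
    )
    return dataset, GroundTruth(
        shared_latents=latents, class_means=means, loadings=loadings
    )
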