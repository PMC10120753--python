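"""Classification metrics and experiment harnesses.

Binary tasks report accuracy, the F1 score of class 1 and the rank-based
AUC; multiclass tasks report accuracy plus the support-weighted and
macro-averaged means of per-class F1. The harnesses mirror the standard
study designs for incomplete multi-omics classification: a missing-rate
sweep, restriction to subsets of omics layers, and an ablation over the
contrastive and attention/auxiliary components.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import accuracy_score, f1_score, roc_auc_score

from .config import TrainConfig
from .data import (
    MultiOmicsDataset,
    SplitSpec,
    simulate_missingness,
    stratified_split,
)
from .model import TrainedModel, train
from .objective import LossWeights

__all__ = [
    "EvalReport",
    "compute_metrics",
    "train_and_evaluate",
    "missing_rate_sweep",
    "layer_combination_study",
    "ablation_study",
    "aggregate_sweep",
]


@dataclass
class EvalReport:
    """Metric bundle for one evaluation.

    ``auc`` is None when the test labels contain a single class (the rank
    statistic is undefined there; it is reported as missing, never as 0).
    """

    task: str
    acc: float
    n_test: int
    f1: float | None = None
    auc: float | None = None
    weighted_f1: float | None = None
    macro_f1: float | None = None
    eta: float | None = None
    config_fingerprint: str | None = None

    def as_dict(self) -> dict:
        return dict(self.__dict__)


def compute_metrics(probs, labels, task: str | None = None,
                    eta: float | None = None,
                    config_fingerprint: str | None = None) -> EvalReport:
    """Score class-probability predictions against integer labels."""
    probs = np.asarray(probs, dtype=np.float64)
    labels = np.asarray(labels, dtype=np.int64)
    if probs.ndim != 2 or probs.shape[0] != labels.shape[0]:
        raise ValueError("probs must be N x C aligned with labels")
    if not np.allclose(probs.sum(axis=1), 1.0, atol=1e-6):
        raise ValueError("probability rows must sum to 1")
    if task is None:
        task = "binary" if probs.shape[1] == 2 else "multiclass"
    predictions = probs.argmax(axis=1)
    acc = float(accuracy_score(labels, predictions))
    if task == "binary":
        f1 = float(f1_score(labels, predictions, pos_label=1, zero_division=0))
        if np.unique(labels).size < 2:
            auc = None
        else:
            auc = float(roc_auc_score(labels, probs[:, 1]))
        return EvalReport(task=task, acc=acc, f1=f1, auc=auc,
                          n_test=labels.size, eta=eta,
                          config_fingerprint=config_fingerprint)
    weighted = float(f1_score(labels, predictions, average="weighted",
                              zero_division=0))
    macro = float(f1_score(labels, predictions, average="macro", zero_division=0))
    return EvalReport(task=task, acc=acc, weighted_f1=weighted, macro_f1=macro,
                      n_test=labels.size, eta=eta,
                      config_fingerprint=config_fingerprint)


def _fingerprint(config: TrainConfig, weights: LossWeights | None = None) -> str:
    w = weights or LossWeights(config.lam_al, config.lam_co, config.lam_cl)
    return (
        f"D={config.latent_dim};epochs={config.epochs};lr={config.lr};"
        f"lam=({w.lam_al},{w.lam_co},{w.lam_cl});alpha={config.alpha};"
        f"seed={config.seed};mode={config.mode};attention={config.attention}"
    )


def train_and_evaluate(
    dataset: MultiOmicsDataset,
    config: TrainConfig,
    split: SplitSpec | None = None,
    weights: LossWeights | None = None,
) -> tuple[TrainedModel, EvalReport]:
    """Train on the split's training rows, score on its test rows."""
    if split is None:
        split = stratified_split(dataset.labels, seed=config.seed)
    fitted = train(dataset.subset(split.train_indices), config, weights=weights)
    test = dataset.subset(split.test_indices)
    probs = fitted.predict_proba(test)
    eta = dataset.meta.get("eta")
    report = compute_metrics(
        probs, test.labels, eta=eta,
        config_fingerprint=_fingerprint(config, weights),
    )
    return fitted, report


def missing_rate_sweep(
    dataset: MultiOmicsDataset,
    config: TrainConfig,
    etas: tuple[float, ...] = (0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8),
    seeds: tuple[int, ...] = (0, 1, 2),
    test_fraction: float = 0.3,
) -> pd.DataFrame:
    """Retrain from scratch at every missing rate x seed.

    ``dataset`` must be fully observed; each cell masks it afresh (both the
    training and the test partition carry the same missing rate), splits,
    trains and scores. Returns one row per (eta, seed).
    """
    if not dataset.mask.mask.all():
        raise ValueError("the sweep expects a fully observed input dataset")
    rows = []
    for eta in etas:
        for seed in seeds:
            masked = (
                simulate_missingness(dataset, eta, seed=seed)
                if eta > 0
                else dataset
            )
            run_config = config.replace(seed=seed)
            split = stratified_split(dataset.labels, test_fraction, seed=seed)
            _, report = train_and_evaluate(masked, run_config, split)
            row = report.as_dict()
            row.update({"eta": eta, "seed": seed})
            rows.append(row)
    return pd.DataFrame(rows)


def aggregate_sweep(table: pd.DataFrame, metric: str = "acc") -> pd.DataFrame:
    """Mean and standard error of a metric per missing rate."""
    grouped = table.groupby("eta")[metric]
    out = grouped.agg(["mean", "sem", "count"]).reset_index()
    out["sem"] = out["sem"].fillna(0.0)
    return out.rename(columns={"mean": f"{metric}_mean", "sem": f"{metric}_se"})


def plot_sweep(table: pd.DataFrame, path, metric: str = "acc") -> None:
    """Write a metric-vs-missing-rate figure (mean +/- s.e. over seeds)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    agg = aggregate_sweep(table, metric)
    fig, ax = plt.subplots(figsize=(5, 3.5))
    ax.errorbar(agg["eta"], agg[f"{metric}_mean"], yerr=agg[f"{metric}_se"],
                marker="o", capsize=3)
    ax.set_xlabel("missing rate")
    ax.set_ylabel(metric)
    ax.set_ylim(0, 1.02)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def layer_combination_study(
    dataset: MultiOmicsDataset,
    config: TrainConfig,
    combos: list[tuple[str, ...]] | None = None,
    eta: float = 0.0,
    seeds: tuple[int, ...] = (0,),
    test_fraction: float = 0.3,
) -> pd.DataFrame:
    """Train and score the model restricted to subsets of omics layers.

    The default combos for three layers are the full triple plus the three
    pairs. With two layers the reconstruction loss reduces to its bi-view
    form automatically.
    """
    if combos is None:
        names = dataset.layer_names
        combos = [tuple(names)] + [
            tuple(n for j, n in enumerate(names) if j != skip)
            for skip in range(len(names) - 1, -1, -1)
        ]
    rows = []
    for combo in combos:
        if len(combo) == 0:
            raise ValueError("a layer combination cannot be empty")
        restricted = dataset.select_layers(list(combo))
        for seed in seeds:
            masked = (
                simulate_missingness(restricted, eta, seed=seed)
                if eta > 0 and len(combo) >= 2
                else restricted
            )
            run_config = config.replace(seed=seed)
            if len(combo) == 1:
                run_config = run_config.replace(mode="complete")
            split = stratified_split(dataset.labels, test_fraction, seed=seed)
            _, report = train_and_evaluate(masked, run_config, split)
            row = report.as_dict()
            row.update({"combo": "+".join(combo), "seed": seed, "eta": eta})
            rows.append(row)
    return pd.DataFrame(rows)


ABLATION_VARIANTS = ("plain", "ctst", "aux", "ctst+aux")


def ablation_study(
    dataset: MultiOmicsDataset,
    config: TrainConfig,
    eta: float = 0.3,
    seeds: tuple[int, ...] = (0, 1, 2, 3, 4, 5, 6, 7, 8, 9),
    test_fraction: float = 0.3,
    variants: tuple[str, ...] = ABLATION_VARIANTS,
) -> pd.DataFrame:
    """Four variants at a fixed missing rate, identical seeds throughout.

    ``plain`` drops both regularizers and bypasses the attention gates;
    ``ctst`` keeps only the contrastive loss; ``aux`` keeps only the gates
    plus the auxiliary-confidence loss; ``ctst+aux`` keeps both. The
    reconstruction loss stays active in all four (it is what handles the
    missing layers; its weight defaults to 0.1 here).
    """
    if config.lam_co <= 0:
        raise ValueError("the ablation requires an active reconstruction loss")
    if not dataset.mask.mask.all():
        raise ValueError("the ablation expects a fully observed input dataset")
    variant_settings = {
        "plain": {"lam_cl": 0.0, "lam_al": 0.0, "attention": "identity"},
        "ctst": {"lam_al": 0.0, "attention": "identity"},
        "aux": {"lam_cl": 0.0, "attention": "gated"},
        "ctst+aux": {"attention": "gated"},
    }
    rows = []
    for seed in seeds:
        masked = simulate_missingness(dataset, eta, seed=seed) if eta > 0 else dataset
        split = stratified_split(dataset.labels, test_fraction, seed=seed)
        for variant in variants:
            if variant not in variant_settings:
                raise ValueError(f"unknown ablation variant {variant!r}")
            run_config = config.replace(seed=seed, **variant_settings[variant])
            _, report = train_and_evaluate(masked, run_config, split)
            row = report.as_dict()
            row.update({"variant": variant, "seed": seed, "eta": eta})
            rows.append(row)
    return pd.DataFrame(rows)
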