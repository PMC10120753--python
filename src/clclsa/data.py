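"""Core data containers, delimited-text I/O and missingness simulation.

A multi-omics dataset is ``M`` numeric matrices (subjects x features), one
per omics layer, with positional subject alignment, an integer class label
per subject and a boolean presence mask saying which layers were measured
for which subject. The missing rate ``eta`` is the fraction of subjects
observing at most ``M - 1`` layers (``eta = N_ic / N``).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "OmicsLayer",
    "PresenceMask",
    "MultiOmicsDataset",
    "SplitSpec",
    "load_dataset",
    "save_dataset",
    "load_saved_dataset",
    "simulate_missingness",
    "stratified_split",
]


@dataclass
class OmicsLayer:
    """One omics modality: a named N x V_i real matrix."""

    name: str
    values: np.ndarray
    feature_names: list[str] | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValueError(f"layer {self.name!r}: values must be 2-D")
        if self.values.shape[1] == 0:
            raise ValueError(f"layer {self.name!r}: feature dimension must be positive")

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]


@dataclass
class PresenceMask:
    """Boolean N x M matrix; entry (j, i) is True iff layer i was observed
    for subject j. Every subject must retain at least one layer."""

    mask: np.ndarray

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 2:
            raise ValueError("presence mask must be 2-D")
        if not self.mask.any(axis=1).all():
            bad = int(np.flatnonzero(~self.mask.any(axis=1))[0])
            raise ValueError(f"subject {bad} has no observed omics layer")

    @property
    def n_incomplete(self) -> int:
        """Number of subjects observing at most M - 1 layers."""
        return int((~self.mask.all(axis=1)).sum())

    @property
    def missing_rate(self) -> float:
        return self.n_incomplete / self.mask.shape[0]

    def observed_pairs(self, i: int, k: int) -> np.ndarray:
        """Boolean vector: subjects observing both layers i and k."""
        return self.mask[:, i] & self.mask[:, k]


@dataclass
class MultiOmicsDataset:
    layers: list[OmicsLayer]
    mask: PresenceMask
    labels: np.ndarray
    n_classes: int | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.layers) < 1:
            raise ValueError("dataset needs at least one omics layer")
        self.labels = np.asarray(self.labels, dtype=np.int64)
        n = self.layers[0].n_subjects
        for layer in self.layers:
            if layer.n_subjects != n:
                raise ValueError(
                    f"layer {layer.name!r} has {layer.n_subjects} rows, expected {n}"
                )
        if self.labels.shape != (n,):
            raise ValueError(f"labels length {self.labels.shape[0]} != {n} subjects")
        if (self.labels < 0).any():
            raise ValueError("labels must be non-negative integers")
        if self.mask.mask.shape != (n, len(self.layers)):
            raise ValueError(
                f"mask shape {self.mask.mask.shape} != ({n}, {len(self.layers)})"
            )
        if self.n_classes is None:
            self.n_classes = int(self.labels.max()) + 1
        observed = self.mask.mask
        for i, layer in enumerate(self.layers):
            rows = observed[:, i]
            if not np.isfinite(layer.values[rows]).all():
                raise ValueError(f"layer {layer.name!r} has non-finite observed values")

    @property
    def n_subjects(self) -> int:
        return self.layers[0].n_subjects

    @property
    def n_layers(self) -> int:
        return len(self.layers)

    @property
    def feature_dims(self) -> tuple[int, ...]:
        return tuple(layer.n_features for layer in self.layers)

    @property
    def layer_names(self) -> list[str]:
        return [layer.name for layer in self.layers]

    def subset(self, indices: np.ndarray) -> "MultiOmicsDataset":
        """Row subset (e.g. a train or test partition)."""
        indices = np.asarray(indices)
        return MultiOmicsDataset(
            layers=[
                OmicsLayer(l.name, l.values[indices], l.feature_names)
                for l in self.layers
            ],
            mask=PresenceMask(self.mask.mask[indices]),
            labels=self.labels[indices],
            n_classes=self.n_classes,
            meta=dict(self.meta),
        )

    def select_layers(self, names: Sequence[str]) -> "MultiOmicsDataset":
        """Restrict to a subset of omics layers, in the given order."""
        if len(names) == 0:
            raise ValueError("at least one layer must be selected")
        index = {layer.name: i for i, layer in enumerate(self.layers)}
        missing = [n for n in names if n not in index]
        if missing:
            raise KeyError(f"unknown layer names: {missing}")
        cols = [index[n] for n in names]
        return MultiOmicsDataset(
            layers=[self.layers[c] for c in cols],
            mask=PresenceMask(self.mask.mask[:, cols]),
            labels=self.labels.copy(),
            n_classes=self.n_classes,
            meta=dict(self.meta),
        )


@dataclass(frozen=True)
class SplitSpec:
    train_indices: np.ndarray
    test_indices: np.ndarray
    seed: int

    def __post_init__(self) -> None:
        train = np.asarray(self.train_indices)
        test = np.asarray(self.test_indices)
        if np.intersect1d(train, test).size:
            raise ValueError("train and test indices overlap")
        object.__setattr__(self, "train_indices", train)
        object.__setattr__(self, "test_indices", test)


# ---------------------------------------------------------------------------
# file I/O


def _read_matrix(path: str | Path) -> tuple[np.ndarray, list[str] | None]:
    """Read a delimited numeric matrix; separator (comma/tab) and an optional
    header row of feature names are auto-detected."""
    path = Path(path)
    with open(path) as fh:
        first = fh.readline()
    sep = "\t" if first.count("\t") >= first.count(",") and "\t" in first else ","
    head = pd.read_csv(path, sep=sep, header=None, nrows=1)
    has_header = head.iloc[0].apply(
        lambda v: isinstance(v, str) and not _is_number(v)
    ).any()
    df = pd.read_csv(path, sep=sep, header=0 if has_header else None,
                     float_precision="round_trip")
    feature_names = [str(c) for c in df.columns] if has_header else None
    for col in range(df.shape[1]):
        coerced = pd.to_numeric(df.iloc[:, col], errors="coerce")
        bad = coerced.isna() & df.iloc[:, col].notna()
        if bad.any():
            row = int(np.flatnonzero(bad)[0])
            raise ValueError(
                f"{path.name}: non-numeric value at row {row}, column {col}"
            )
        df.iloc[:, col] = coerced
    return df.to_numpy(dtype=np.float64), feature_names


def _is_number(text: str) -> bool:
    try:
        float(text)
        return True
    except ValueError:
        return False


def load_dataset(
    layer_paths: Sequence[str | Path],
    label_path: str | Path,
    mask_path: str | Path | None = None,
    layer_names: Sequence[str] | None = None,
) -> MultiOmicsDataset:
    """Assemble a dataset from per-omics matrix files, a label file and an
    optional 0/1 presence-mask file. With no mask file all layers are taken
    as observed. Subject alignment is positional (row j everywhere is the
    same subject)."""
    if layer_names is None:
        layer_names = [Path(p).stem for p in layer_paths]
    layers = []
    n_ref: int | None = None
    for name, path in zip(layer_names, layer_paths):
        values, feats = _read_matrix(path)
        if n_ref is None:
            n_ref = values.shape[0]
        elif values.shape[0] != n_ref:
            raise ValueError(
                f"{Path(path).name}: {values.shape[0]} rows, expected {n_ref}"
            )
        layers.append(OmicsLayer(str(name), values, feats))
    labels_raw = pd.read_csv(label_path, header=None).iloc[:, 0].to_numpy()
    labels = np.asarray(labels_raw, dtype=np.int64)
    if labels.shape[0] != n_ref:
        raise ValueError(
            f"{Path(label_path).name}: {labels.shape[0]} labels, expected {n_ref}"
        )
    if mask_path is not None:
        mask_values, _ = _read_matrix(mask_path)
        mask = PresenceMask(mask_values.astype(bool))
    else:
        mask = PresenceMask(np.ones((n_ref, len(layers)), dtype=bool))
    return MultiOmicsDataset(layers=layers, mask=mask, labels=labels)


def save_dataset(dataset: MultiOmicsDataset, out_dir: str | Path) -> Path:
    """Write the dataset as a directory of delimited files plus metadata."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for layer in dataset.layers:
        df = pd.DataFrame(layer.values, columns=layer.feature_names)
        # %.17g round-trips float64 exactly
        df.to_csv(out_dir / f"{layer.name}.csv", index=False,
                  header=layer.feature_names is not None, float_format="%.17g")
    pd.DataFrame(dataset.labels).to_csv(out_dir / "labels.csv",
                                        index=False, header=False)
    pd.DataFrame(dataset.mask.mask.astype(int)).to_csv(
        out_dir / "mask.csv", index=False, header=False
    )
    meta = {
        "layer_names": dataset.layer_names,
        "feature_dims": list(dataset.feature_dims),
        "n_subjects": dataset.n_subjects,
        "n_classes": dataset.n_classes,
        **dataset.meta,
    }
    with open(out_dir / "metadata.json", "w") as fh:
        json.dump(meta, fh, indent=2)
    return out_dir


def load_saved_dataset(in_dir: str | Path) -> MultiOmicsDataset:
    """Inverse of :func:`save_dataset`."""
    in_dir = Path(in_dir)
    with open(in_dir / "metadata.json") as fh:
        meta = json.load(fh)
    names = meta["layer_names"]
    ds = load_dataset(
        [in_dir / f"{name}.csv" for name in names],
        in_dir / "labels.csv",
        in_dir / "mask.csv",
        layer_names=names,
    )
    ds.meta = {k: v for k, v in meta.items()
               if k not in ("layer_names", "feature_dims", "n_subjects", "n_classes")}
    return ds


# ---------------------------------------------------------------------------
# missingness


def simulate_missingness(
    dataset: MultiOmicsDataset, eta: float, seed: int
) -> MultiOmicsDataset:
    """Mask omics layers so that exactly ``round(eta * N)`` subjects become
    incomplete.

    For each incomplete subject the number of surviving layers is drawn
    uniformly from {1..M-1} and the surviving layer identities uniformly
    without replacement. Masked values stay in storage; only the presence
    mask changes. Deterministic given ``seed``.
    """
    if not 0.0 <= eta <= 1.0:
        raise ValueError(f"eta must be in [0, 1], got {eta}")
    if not dataset.mask.mask.all():
        raise ValueError("simulate_missingness expects a fully observed dataset")
    n, m = dataset.n_subjects, dataset.n_layers
    rng = np.random.default_rng(seed)
    n_incomplete = int(round(eta * n))
    mask = np.ones((n, m), dtype=bool)
    if n_incomplete > 0 and m >= 2:
        subjects = rng.choice(n, size=n_incomplete, replace=False)
        for j in subjects:
            n_observed = int(rng.integers(1, m))
            keep = rng.choice(m, size=n_observed, replace=False)
            mask[j] = False
            mask[j, keep] = True
    new_meta = dict(dataset.meta)
    new_meta.update({"eta": eta, "mask_seed": seed})
    return MultiOmicsDataset(
        layers=[OmicsLayer(l.name, l.values.copy(), l.feature_names)
                for l in dataset.layers],
        mask=PresenceMask(mask),
        labels=dataset.labels.copy(),
        n_classes=dataset.n_classes,
        meta=new_meta,
    )


def stratified_split(
    labels: np.ndarray, test_fraction: float = 0.3, seed: int = 0
) -> SplitSpec:
    """Seeded random split keeping class proportions; every class present in
    the data appears in the training partition."""
    labels = np.asarray(labels)
    rng = np.random.default_rng(seed)
    train_idx: list[int] = []
    test_idx: list[int] = []
    for cls in np.unique(labels):
        members = np.flatnonzero(labels == cls)
        members = rng.permutation(members)
        n_test = int(round(test_fraction * members.size))
        n_test = min(n_test, members.size - 1)  # keep >=1 training example
        test_idx.extend(members[:n_test])
        train_idx.extend(members[n_test:])
    return SplitSpec(
        train_indices=np.sort(np.array(train_idx, dtype=np.int64)),
        test_indices=np.sort(np.array(test_idx, dtype=np.int64)),
        seed=seed,
    )

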