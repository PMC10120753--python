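import numpy as np
import pytest

from clclsa import MultiOmicsDataset, OmicsLayer, PresenceMask, SyntheticSpec, generate


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_dataset():
    """60 subjects, 3 layers, well-separated binary classes."""
    spec = SyntheticSpec(
        n_subjects=60,
        feature_dims=(12, 12, 8),
        class_separation=4.0,
        noise_sd=1.0,
        sample_seed=3,
    )
    dataset, _ = generate(spec)
    return dataset


@pytest.fixture
def toy_dataset():
    """Five subjects, two tiny layers, fixed values (for exact arithmetic)."""
    rng = np.random.default_rng(0)
    x1 = rng.normal(size=(5, 3))
    x2 = rng.normal(size=(5, 2))
    labels = np.array([0, 1, 0, 1, 1])
    return MultiOmicsDataset(
        layers=[OmicsLayer("a", x1), OmicsLayer("b", x2)],
        mask=PresenceMask(np.ones((5, 2), dtype=bool)),
        labels=labels,
    )
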