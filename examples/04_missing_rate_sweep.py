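"""Sweep the missing rate and watch classification degrade.

Retrains from scratch at each missing rate (applied to train and test
alike) and reports mean accuracy with its standard error over seeds.
"""

from clclsa import (
    SyntheticSpec,
    TrainConfig,
    aggregate_sweep,
    generate,
    missing_rate_sweep,
)

dataset, _ = generate(
    SyntheticSpec(n_subjects=120, feature_dims=(30, 30, 20),
                  class_separation=2.5)
)
config = TrainConfig(latent_dim=16, epochs=150, seed=0)
table = missing_rate_sweep(dataset, config,
                           etas=(0.0, 0.3, 0.6), seeds=(0, 1))
print(aggregate_sweep(table).to_string(index=False))
# Accuracy should fall (noisily) as more subjects lose omics layers; at
# eta=0 there is no masking, so results do not depend on the mask seed.
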