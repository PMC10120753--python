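"""Generate a synthetic multi-omics cohort and simulate missing layers.

Builds three omics layers (e.g. mRNA, methylation, miRNA stand-ins) that
are noisy linear views of one class-dependent latent factor, then masks
layers so 30% of subjects are incomplete.
"""

from clclsa import SyntheticSpec, generate, simulate_missingness

spec = SyntheticSpec(
    n_subjects=120,
    feature_dims=(50, 50, 30),
    n_classes=2,
    class_separation=4.0,  # distance between class means in latent space
    noise_sd=1.0,
)
dataset, truth = generate(spec)
masked = simulate_missingness(dataset, eta=0.3, seed=0)

print(f"subjects: {dataset.n_subjects}, layers: {dataset.layer_names}")
print(f"feature dims: {dataset.feature_dims}, classes: {dataset.n_classes}")
print(f"missing rate: {masked.mask.missing_rate:.2f} "
      f"({masked.mask.n_incomplete} incomplete subjects)")
print(f"observed layers per subject (first 10): "
      f"{masked.mask.mask.sum(axis=1)[:10].tolist()}")
# The missing rate is the fraction of subjects observing at most M-1 of
# the M layers; each incomplete subject keeps between 1 and M-1 layers.
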