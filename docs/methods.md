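# Methods

## The model

`clclsa` classifies subjects from `M` omics layers (e.g. mRNA expression,
DNA methylation, miRNA expression) when some subjects are missing some
layers. A cohort is `M` matrices `X_i` of shape `N x V_i` with positional
subject alignment, an integer label per subject, and a boolean presence
mask; the missing rate `eta = N_ic / N` is the fraction of subjects
observing at most `M - 1` layers.

Four mechanisms combine into one trained network:

1. **Self-attention gating.** Per layer, a feature gate
   `fatt = sigma(f_i(x))` (one sigmoid per input feature) and an omics gate
   `matt = sigma(g_i(x_hat))` (one sigmoid per subject). The embedded,
   gated latent is `z_hat_i = matt * emb_i(x * fatt)`. The printed form of
   the feature gate multiplies the *embedding output* by a gate of *input*
   width, which is ill-typed whenever `V_i != D_i`; we gate the input by
   default and expose the post-embedding alternative
   (`gate_convention="output"`, valid only for width-preserving
   embeddings).
2. **Cross-omics completion.** For each ordered layer pair `(i, k)` a
   translator `h_ik = dec_i o enc_k` maps layer-`k` latents into
   layer-`i` latent space (`M(M-1)` translators, default architecture
   `D-64-BN-ReLU-32-ReLU-64-BN-ReLU-D`). They are supervised by the squared
   error against latents computed from really-observed data; a missing
   `(subject, layer)` latent is imputed as the unweighted mean of the
   translations from the subject's observed layers. Imputation happens in
   latent space only.
3. **Cross-view contrastive alignment.** Latents are mapped row-wise
   through a softmax so each subject is a distribution over latent
   dimensions; the pairwise joint distribution is
   `P = (1/N) sum_j outer(s_i, s_k)` (symmetrized and renormalized when
   square). The loss
   `-sum P_dd' ln(P_dd' / (P_d^{a+1} P_d'^{a+1}))`
   is minus the mutual information between the views' latent-dimension
   variables plus `alpha` times their marginal entropies. The softmax
   projection is required for `P` to be a probability matrix at all, since
   raw latents are unconstrained. Layer pairs are summed in ordered form
   (each unordered pair twice); `pairs="unordered"` halves the total.
4. **Confidence-regularized classification.** The fused vector
   `z = [z_hat_1, ..., z_hat_M]` feeds one softmax classifier
   (cross-entropy `L_clf`). Per layer, an auxiliary softmax head adds
   `(matt_i - conf_i)^2 + CE_i`, tying the omics gate to the head's
   confidence. `conf` is the head's maximal softmax output by default
   (`confidence="true-class"` uses the true-class probability instead).
   The squared term exists only where a layer was actually observed
   (gates are computed from real inputs); the cross-entropy term also
   covers imputed entries unless disabled.

The composite objective is
`L = L_clf + lam_al L_al + lam_co L_co + lam_cl L_cl`, reported
component-wise at every step. In complete-data mode `lam_co` is pinned to
zero (there is nothing to complete). A confidently-wrong printed form of
the auxiliary cross-entropy (`+ y log y_hat`) would be unbounded below;
we minimize the conventional negative cross-entropy.

## Training

Full-batch Adam at learning rate 1e-4 with step decay x0.2 every 500
epochs; dropout probability 0.5 in the embedding stacks; weights
initialized fan-in-scaled uniform from one seeded generator per run, so a
`(config, seed)` pair reproduces losses and metric reports exactly. Each
epoch: forward every training subject; supervise each translator `h_ik`
on subjects observing both `i` and `k` (strictly more supervision than
complete-subjects-only, which remains available via
`co_supervision="complete-only"`); complete missing latents with the
current translators (imputed rows are detached by default so the
classifier path does not steer translators mid-training); one optimizer
step on the combined objective. The reconstruction loss averages over
latent dimensions and supervised subjects by default for scale stability
(`co_form="sum"` restores the plain squared-norm sum). Training with an
active reconstruction loss requires at least one fully observed subject;
otherwise it raises.

Balance factors default to `lam_al=0.1, lam_co=0.1, lam_cl=0.01` with the
grid `{0, 0.01, 0.02, 0.05, 0.1, 1.0}` available through `grid_search`
(180 cells in incomplete mode, where `lam_co > 0`; 36 in complete mode),
selected by validation accuracy with ties broken by lower final loss then
lexicographic weights. `alpha` defaults to 9.0, following the convention
of the contrastive-alignment lineage this loss comes from.

## The synthetic generator

All layers are noisy linear views of one shared latent factor: subject
`j` of class `y` draws `s ~ Normal(mu_y, I_d)` with class means at the
vertices of a regular simplex at mutual distance `class_separation`
(balanced labels up to remainder), and layer `i` observes
`X_i[j] = s W_i + eps_i`, `eps_i ~ Normal(0, sd_i^2)`. Defaults: N=200,
M=3, C=2, V=(50, 50, 30), d_shared=5, separation 4.0, noise 1.0 — a task
where each single layer is linearly separable and the full pipeline
reaches held-out accuracy above 0.9 within 300 epochs. Three optional
departures from the plain dense model, all off by default:

- per-layer noise levels (`noise_sd` as a tuple) — platforms differ in
  signal-to-noise;
- sparse loadings (`signal_fraction`) — only a fraction of features carry
  the factor, the few-differential-genes regime;
- per-subject corruption (`corrupt_fraction`, `corrupt_scale`) — a random
  subset of (subject, layer) measurements is replaced by pure
  high-variance noise, emulating degraded samples or failed assays, so
  modality *reliability varies per subject*.

What the generator does not emulate: omics marginal distributions
(counts, beta-values), batch structure, feature correlation beyond the
shared factor. Passing tests therefore demonstrate mechanism correctness
and qualitative behavior, not performance on real cohorts.

## Study designs and problem sizes

The built-in studies run at desk scale, chosen so the full suite trains
dozens of models on one CPU:

- **End-to-end / imputation.** N=200 (separation 4) and N=300 (noise
  0.2) respectively, 300 epochs, latent width 16. Imputation quality is
  the fraction of held-out subjects whose translator-imputed latent is
  closer in cosine to the encoder's real-input latent than the mean
  training latent is; this exceeds 0.9 across all three layers.
- **Missing-rate sweep.** N=150, V=(30, 30, 20), separation 2.5, etas
  0 to 0.8, three seeds, retraining from scratch per cell; the same eta
  is applied to train and test partitions (exposed as a choice; nothing
  in the problem statement distinguishes them).
- **Component ablation.** Four variants with identical seeds: plain
  (gates bypassed as identity, `lam_al = lam_cl = 0`), ctst, aux,
  ctst+aux, all with `lam_co = 0.1`. The benchmark dataset uses
  per-subject corruption (fraction 0.35, scale 3), because on the plain
  isotropic generator the gated and plain variants converge to the same
  solution — there is no per-subject reliability signal for the gates to
  exploit, and we verified the variants' converged accuracies coincide
  there. Study weights `lam_al=0.01, lam_co=0.1, lam_cl=0.01` were fixed
  once by validation grid search on an inner split. Even so, the measured
  full-vs-plain gap at this scale is small (about +0.01 accuracy over ten
  seeds, within one standard error): the omics gates move little from
  their 0.5 initialization within a 600-epoch budget, and the ablation
  contrast is intrinsically weaker on linear-Gaussian data than on real
  cohorts. We report the gap rather than overstating it.

## Numerical choices

- Probabilities are clamped at 1e-12 inside logarithms; `0 * ln 0 = 0` by
  construction (zero entries multiply the log term).
- Softmax subtracts a detached row max; the logistic uses the two-branch
  stable form.
- `max` gradients split evenly across ties, so finite-difference checks
  hold even at ties.
- Batch-norm layers use batch statistics while training and running
  statistics in evaluation; completion always applies translators in
  evaluation mode, so imputation does not depend on how many rows are
  missing in a batch.
- Gradient checks (central differences, 1e-4 relative) run in evaluation
  mode, where the loss is a pure function of the weights.
- AUC is undefined for single-class test labels and reported as missing,
  never as 0.

## Known limitations

- The feature gate `f_i` is a `V_i x V_i` linear map; for wide layers it
  dominates the parameter count and can overfit small cohorts.
- A single linear omics gate can only threshold along one direction of
  the embedded latent, so its ability to detect off-manifold (corrupted)
  inputs is limited; this bounds the ablation contrast above.
- Full-batch training is assumed; minibatching is not implemented.
- No raw-feature-space imputation, by design.
- The train/test protocol is a seeded stratified split (default 70/30);
  benchmark-specific split conventions from prior pipelines are not
  reproduced.
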