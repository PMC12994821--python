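# Methods

This note documents the models, procedures and numerical choices behind
`aetrans`, the assumptions they rest on, and what the synthetic benchmark
does and does not demonstrate.

## Setting and pairing strategy

The package addresses case–control classification from two molecular
modalities measured on *disjoint* sets of individuals: a gene-expression
cohort and a DNA-methylation cohort (beta values in [0, 1]), each with a
binary diagnosis label. Because no sample-level correspondence exists,
training examples are synthetic pairs: the Cartesian product of same-label
samples across modalities (case × case, control × control). Two assumptions
are implicit and worth stating:

1. the biological class signal is (partly) shared across modalities, so a
   pair of same-label individuals is a meaningful joint observation; and
2. pair-level supervision is label-only — the model never sees which pairs
   are "really" the same person, because none are.

All splits and cross-validation folds are drawn on **samples** per modality,
stratified by class, before any pairing; pairs are re-enumerated inside each
split or fold. This makes leakage structurally impossible (asserted by the
training loop and the test suite). Because the full Cartesian corpus grows
as |cases|·|cases| + |controls|·|controls|, each training epoch instead
visits label-consistent minibatches: `rna_per_batch` expression samples
(default 32) drawn without replacement within the batch, each paired with
`meth_per_rna` (default 2) same-label methylation samples.

Evaluation is reported per pair (the default metric surface) and per
expression sample (mean predicted probability over that sample's test
pairs); neither view is privileged, both are exposed.

## Preprocessing

Probe-level inputs become gene-level matrices by: (i) arithmetic averaging
of probes mapped to the same gene, over observed values only, discarding
unannotated probes; (ii) for methylation, retaining only CpG probes within
1500 bp upstream of a transcription start site (`tss_offset` is signed,
negative = upstream, so the window is [−1500, 0]) and dropping probes
annotated to more than one gene; (iii) removing features missing in more
than 30% of samples and setting remaining missing entries to exactly zero;
(iv) intersecting the two gene sets in lexicographic order; and (v)
per-feature z-scoring with training-set statistics (zero-variance features
are scaled by 1). Zero-imputation precedes standardization, and
standardization statistics are never recomputed on test data. Batch
harmonization is a pluggable hook with a per-batch mean-centering default;
empirical-Bayes methods are deliberately out of scope.

## Architecture

Per modality: a two-hidden-layer autoencoder (encoder activations
ReLU/ReLU; decoder ReLU then sigmoid, so reconstructions live in (0, 1)).
The latent vector (default 128 = 8 tokens × 16 channels in the full-size
configuration) is reshaped into a token grid — the minimal way to present a
latent vector to a Transformer; the tokenization is config-exposed.
Sinusoidal positional encoding is added (the reshaped tokens have no
natural order, but the encoding gives the attention layers a consistent
coordinate system and is retained by design). Each modality then passes
through a stack of post-norm Transformer encoder layers (sublayer → add →
LayerNorm; default 3 layers, 4 heads, matching the original Transformer's
residual ordering). Flattened encoder outputs are concatenated, linearly
fused, and classified by a sigmoid-terminated ReLU MLP.

Cross-modal alignment: the fused vector is re-tokenized and two
modality-specific Transformer decoder paths (self-attention,
cross-attention over the fused tokens, feed-forward; default 1 layer, which
keeps the desk-scale model fast — depth is configurable) produce latent
tokens that the *target* modality's autoencoder decoder maps back to input
space. Because the fused vector depends on both encoders, each cycle
reconstruction backpropagates into the opposite modality's channel — the
coupling that aligns the two latent spaces (verified by a gradient test).

During training only, input features are independently zeroed with
probability `mask_rate` (default 0.1) — denoising-style input masking. The
loss is a weighted sum of five terms (weights default to 1.0): BCE for
classification, per-modality own-path reconstruction MSE (from each
modality's own latent), and per-modality cycle MSE (through the fused
path). Own-path reconstructions use the AE latent directly; cycle
reconstructions use the fused representation — reconciling the two
reconstruction roles the architecture needs. Since inputs are z-scored but
decoders are sigmoid-bounded, the reconstruction terms have a floor; they
act as regularizers that shape the latent space rather than as exact
autoencoding objectives, and both their totals and the cycle terms decrease
over training (asserted in the run manifest).

## Training

Adam (initial learning rate 0.001) with classic L2 weight decay; a
plateau scheduler halves the learning rate after 5 non-improving validation
epochs (min 1e−6); early stopping after 15 non-improving epochs; the
best-validation checkpoint is returned. Stratified five-fold CV realizes
"balanced positive and negative samples" as stratification, not
re-sampling. Everything is a pure function of the config seed: two runs
with identical configs produce identical metrics.

The **desk-scale reference configuration** used throughout the examples,
tests and acceptance script is: AE hidden 32, latent 32 (4 tokens × 8
channels), 2 encoder layers, 1 decoder layer, 4 heads, FFN hidden 32, MLP
hidden (32,), mask rate 0.1, weight decay 1e−2, ≤60 epochs. The strong
weight decay is what stops this small network from memorizing cohorts of a
few hundred samples; it was chosen by a small sweep on the default
synthetic cohort and then frozen. A full-size configuration (hidden 512,
latent 128, 3 encoder layers) is the architecture default but is not needed
at synthetic scale.

Single-modality fine-tuning freezes both autoencoders and the whole
methylation channel, feeds the methylation input a zero placeholder, and
updates the expression Transformer encoder, the classifier head and (by
default, flag-controlled) the fusion layer, on classification loss only.
The classifier head stays trainable because a frozen head cannot adapt to a
new cohort's calibration. Per-sample fused latents are exported for
downstream clustering or probing.

## Attribution

Integrated gradients along the straight path g(α) = x′ + α(x − x′):

score_i = (x_i − x′_i) · (1/n) Σ_j ∂F(g(α_j))/∂x_i.

Numerical choices:

- **Quadrature.** Default `midpoint` (α_j = (j−½)/n): its O(1/n²) error
  keeps the completeness gap |Σ score − (F(x) − F(x′))| below 1% of
  |F(x) − F(x′)| at n = 256 on the trained reference model. The plain
  right-endpoint summation (α_j = j/n) is available as `rule="right"`; its
  O(1/n) error is measurably too large for the 1% completeness target at
  n = 256 (2–10% across model seeds), which is why it is not the default.
- **Baseline.** All-zeros by default — in standardized coordinates this is
  the cohort mean, a neutral counterfactual; all-ones and custom vectors
  are config-exposed. "Counterfactual" IG here means IG against this
  documented reference; no separate formula is involved.
- **Steps.** Default n = 64 for ranking (ranking is insensitive to n well
  before completeness is tight); n = 256 when completeness itself is
  measured.
- **Aggregation.** Per-feature mean of |score| across attributed pairs
  (default), or the signed mean; the cross-sample average is unweighted.
  Rankings are reported **per modality**: IG score scales differ
  systematically between the expression and methylation blocks, so a
  pooled ranking would mostly reflect that scale difference. Fold-averaged
  attribution (each CV fold's model attributing its own validation pairs,
  scores averaged feature-wise) is provided for stability.

Validation of a ranking uses: a sparse L2-logistic classifier on the top-k
features (with random-k, variance, univariate-F and PCA comparators under
the same backbone); stepwise ablation that zero-masks rank bands and
retrains from scratch against an equal-size random control band; and a
Pearson co-expression network over top features (edges at |r| > 0.75,
constant features excluded, connected components labeled).

## Metrics

Confusion counts at threshold 0.5 (score ≥ threshold ⇒ positive; the
boundary convention is documented and the threshold exposed). Accuracy,
precision, recall and F1 by the standard formulas; zero-denominator ratios
are reported as 0 with an explicit flag rather than NaN. ROC/AUC by a
threshold sweep over grouped unique scores and the trapezoidal rule, which
equals the Mann–Whitney concordance probability with ties counted ½
(verified to 1e−9 against a brute-force pair count). Modality ablation
retrains fused, expression-only and methylation-only conditions under
identical seeds, feeding the withheld channel zeros and dropping its loss
terms, so parameter counts stay comparable; both held-out test metrics and
(optionally) CV means are tabulated — CV means are the right quantity for
null-signal checks, where a single small test split is too noisy.

## Synthetic benchmark: what it emulates and what it does not

The generator draws per-sample latent factors z ~ N(0, I); the diagnosis
shifts the first factor by `latent_shift` (default 3) within-class standard
deviations in cases. Informative features load on that factor with
coefficient `effect_size / latent_shift`, so their class-conditional means
differ by exactly `effect_size` (default 1.5) before noise — in the linear
predictor for methylation, which passes a logistic squash into beta values
plus truncated noise. Non-informative features are pure noise. The two
cohorts are generated independently (different sizes, disjoint sample ids):
unpairedness is structural, not simulated by shuffling.

The latent separation default matters: it controls the irreducible overlap
of the shared factor, which bounds any classifier's achievable AUC
regardless of feature count. Three standard deviations emulates the
near-separable case–control cohorts on which this class of model is
typically reported, while leaving feature-level difficulty to `effect_size`
and `noise_sd`. The default cohort is 200 expression / 120 methylation
samples, 400 genes, 20 informative per modality — sizes chosen so every
pipeline stage runs in seconds on one CPU while keeping class counts
realistic for a small clinical study.

Passing tests on this benchmark show that the implementation recovers a
known cross-modal signal, ranks injected features highly, and degrades when
they are removed. They do **not** show robustness to batch effects,
platform noise, probe-level artifacts, confounded labels, class imbalance
beyond the configured fraction, or biological correlation structure beyond
a low-rank factor model — real cohorts have all of these, and the
preprocessing hooks (batch centering, missingness filtering) only partially
address them.

## Degenerate inputs and edge conventions

Single-class cohorts, empty feature intersections, all-missing features,
classes too small to split, shape mismatches and invalid configurations
raise typed errors naming the offending field. Constant features z-score to
zero (scale forced to 1) and are excluded from correlation networks with a
warning. Predicted probabilities are clipped to [1e−7, 1 − 1e−7] inside the
BCE with a warning if they ever leave (0, 1). Checkpoints are single-file
archives of config JSON plus named weight arrays, loadable by name across
versions.

## Known limitations

- The pair corpus squares the effective training-set size without adding
  independent information; per-pair metrics therefore overstate the
  effective n (the per-sample view is the conservative one).
- The numpy autodiff engine is single-threaded and eager; it is sized for
  desk-scale experiments (hundreds of samples, hundreds to thousands of
  features), not for full-genome inputs or the 377M-parameter regime.
- The mask mechanism (input zeroing) and the IG cross-sample "weighted
  average" (implemented unweighted) are documented reconstructions of
  under-specified components; both are config-exposed.
- Methylation-specific noise (probe chemistry, bimodality of beta values
  across CpG contexts) is only coarsely emulated by the logistic-squash
  model.
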