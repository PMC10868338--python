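# Methods

## Data model and preprocessing

All analyses operate on an annotated cell-by-feature matrix (`OmicsDataset`)
with cells as rows everywhere; Matrix Market triplet directories and
10x-style HDF5 files, which store features-by-cells, are transposed on read.
A `layer_state` flag distinguishes raw counts from log-normalized values and
is enforced as a precondition of every operation (filters require counts,
model fits require lognorm), which turns silent scale bugs into immediate
errors.

Preprocessing follows the standard recipe: count filters keep features/cells
with total counts at or above a threshold (both filters use `>=`, one
consistent convention), library-size normalization rescales each cell to a
common total (default 10,000) followed by `log1p`, and highly variable genes
are ranked by the variance-to-mean dispersion of log-normalized values with
ties resolved toward earlier columns. Datasets are combined over the
*intersection* of feature names (in the first dataset's order) rather than a
zero-filled union: fabricated zeros would be read by the encoders as
biology.

## Variational integration models

All three integration models are variational autoencoders sharing one
backbone: an encoder MLP (hidden sizes 128, 64, ReLU) producing a diagonal
Gaussian posterior `q(z|x) = N(mu, diag(exp(logvar)))` over a
16-dimensional latent, the closed-form KL against the standard-normal
prior, reparameterized sampling, and a decoder MLP with a Gaussian
likelihood whose per-feature variance is a learned free parameter. Inputs
are per-feature z-scored inside the fit (and un-scored on decode): this
keeps every feature's reconstruction term on a comparable scale and
markedly improves latent quality on overdispersed count data. The loss is
`recon + beta*KL` with `beta = 1` by default.

Model-specific structure:

- **Conditional model (unpaired).** The decoder input is `[z, one-hot(b)]`
  where `b` is the batch of origin, so batch-specific shifts are explained
  by the condition and `z` is free to encode shared structure. The
  batch-corrected matrix decodes every cell's posterior mean under one fixed
  reference code (the first dataset), making corrected profiles comparable
  across batches by construction.
- **Domain-adversarial model (unpaired).** The decoder sees `z` only.
  Batch invariance is enforced by a one-hidden-layer softmax classifier on
  the sampled `z`: the classifier descends the domain cross-entropy (five
  inner Adam steps per minibatch with its own optimizer, lr 1e-2 — a strong
  critic gives the encoder an up-to-date reversal direction), while the
  encoder receives that gradient *reversed*, scaled by the adversarial
  weight times a fixed factor of 30. The factor compensates for the O(1)
  scale of the cross-entropy against a reconstruction term summed over
  hundreds of features; without it the adversary is cosmetic and the latent
  remains perfectly batch-separable.
- **Multi-view model (paired).** The encoder consumes the concatenation of
  both views (early fusion), yielding a single posterior per cell; two
  view-specific decoders reconstruct each modality and their reconstruction
  terms add. Early fusion is the simplest faithful multi-view reading; a
  product-of-experts posterior would be the natural swap-in if views with
  missing cells ever needed support.

**Training.** Minibatch Adam (batch 128, lr 1e-3, 50 epochs, no schedule).
Two stabilizers are built in, both standard practice for VAEs: the KL
weight (and the adversarial weight) anneal linearly from zero over the
first half of training — without warm-up the posterior collapses
(`KL -> 0`) and the latent carries nothing — and the adversary additionally
stays off for the first quarter of the ramp so the two-player game starts
only after a structured latent exists. Configured weights are fully in
force for the entire second half, so converged traces reflect them exactly.
Every source of randomness (initialization, shuffling, reparameterization
noise) derives from one generator seeded by `TrainingConfig.seed`; fits are
bit-reproducible on one platform, and cross-platform agreement is only
promised to ~1e-4 on loss traces. Cells are internally sorted by (batch,
cell name) before training and outputs returned in caller order, so results
are invariant to input row order. The per-epoch loss trace records
`(total, reconstruction, KL, adversarial)` with the KL and adversarial
columns unweighted.

**Label transfer.** Majority vote among the `k` Euclidean-nearest reference
cells in the shared latent space; ties break toward the label with smaller
mean neighbor distance, then lexicographically. Confidence is the winning
vote fraction.

## Spatially variable gene test

Per gene, expression (log-normalized, then standardized to zero mean and
unit variance) is modeled as

```
y ~ N(mu * 1,  sigma_s^2 * K(l) + sigma_n^2 * I),
K_ij = exp(-||s_i - s_j||^2 / (2 l^2)),
```

and the test statistic is the log-likelihood ratio of this model against
the iid null (`sigma_s^2 = 0`), maximized over a fixed grid of 10
log-spaced lengthscales spanning the minimum-nonzero to maximum pairwise
spot distance. At each lengthscale the fit is exact, not approximate:
writing the covariance as `v * (f*K + (1-f)*I)` with spatial fraction
`f = sigma_s^2/(sigma_s^2+sigma_n^2)`, both `mu` and the total variance `v`
have closed-form maximizers, leaving a 1-D bounded search over `f`
(coarse grid plus Brent refinement). Each grid kernel is eigendecomposed
once per dataset, making every likelihood evaluation O(n) after projecting
`y` onto the eigenbasis; a full 200-gene scan on 100 spots takes ~2 s.

Because `sigma_s^2 = 0` lies on the boundary of the parameter space, the
null distribution of twice the LLR is taken as the 50:50 mixture of a point
mass at zero and chi-square(1): `p = 0.5 * P(chi2_1 >= 2*llr)`, `p = 1` when
`llr = 0`. With 200 iid-normal null genes on a 10x10 grid the empirical
rejection rate at alpha 0.05 is 0.05 despite the maximization over the
lengthscale grid. A permutation mode (expression shuffled over spots,
`p = (1 + #{perm >= obs}) / (1 + n_perm)`) is the assumption-free fallback
and ranks genes concordantly with the mixture p-values (Spearman > 0.99 in
the suite's mixed simulation). Gene-level p-values are Benjamini-Hochberg
adjusted; the scan returns genes sorted by p, ties by descending LLR.
Numerically constant genes (relative sd below 1e-10) short-circuit to
`llr = 0, p = 1` and are flagged degenerate.

The exact-marginal formulation doubles as its own oracle: the standalone
`gp_log_marginal` evaluates the same quantity via Cholesky with jitter
escalation (up to 1e-3) and is checked against a dense inverse/determinant
computation to 1e-8.

## Synthetic data

The generators define the package's study conditions; their defaults are
fixed once and every quality number in the test suite refers to them.

- **Unpaired batches** (default 2 x 500 cells, 200 genes, 3 types):
  per-gene base log-means ~ N(0,1); each type perturbs a random 20% of
  genes with N(0, 1) effects (a strong type signal); each batch adds
  N(0, 0.5^2) per-gene offsets (a moderate batch effect); library sizes
  log-normal (sigma 0.3); counts negative binomial with inverse-dispersion
  2 — typical scRNA-seq overdispersion. Type proportions are identical
  across batches.
- **Paired views** (default 500 cells; 200 + 60 features): one latent type
  per cell drives both views through independent loadings; the smaller
  second view plants effects on 50% of its features, mimicking a curated
  antibody or accessibility panel in which most features discriminate
  populations, so each view is individually informative (per-view PCA
  k-means ARI ~0.96).
- **Spatial lattice** (default 10x10 spots, 200 genes, 20 spatially
  variable): patterns on the log scale — a linear gradient spanning
  amplitude `a` across the tissue, a Gaussian hotspot of radius one quarter
  of the grid, a two-period sinusoid — added to iid N(0, 1) log-noise,
  exponentiated, Poisson-sampled. Pattern coordinates are scaled to the
  unit square so amplitude means the same thing at every grid size.

What the generators do *not* emulate: dropout beyond NB/Poisson sampling,
peak-level ATAC structure, doublets, spatial platform artifacts, or
mean-variance trends across genes. Passing quality gates on these data
shows the machinery is correct and well-calibrated, not that it matches
state-of-the-art integration on real tissue atlases.

A known consequence of the chosen spatial conditions: with baseline
log-mean 0 (~1.7 counts per spot) the planted hotspot patterns carry a
count-level spatial variance fraction of only ~0.15, and the scan recovers
11 of 20 planted genes at FDR 0.05 (all periodic, most gradients, no
hotspots). The limitation is count depth, not the test: on the same
patterns without Poisson sampling the scan detects 16/20 of the hotspots
alone, calibration is exact, and lengthscale recovery on direct GP draws is
20/20. The conditions are kept as chosen rather than tuned until every
pattern clears the threshold.

## Numerical choices and limitations

- Posterior log-variances are clamped to [-8, 8] (gradients masked outside).
- Weight init is uniform with 1/sqrt(fan-in) scaling from the run's seed;
  biases start at zero.
- k-means (for ARI) uses 10 seeded restarts; nearest-neighbor queries use
  exact search (scikit-learn).
- Batch-mixing entropy excludes the cell itself from its neighborhood and
  is defined as 0 when only one batch exists.
- The GP test assumes Gaussian residuals after log-normalization; for very
  low counts this understates the information in the data (see above), and
  a count likelihood would be the principled extension.
- Only 2-D coordinates and the squared-exponential kernel are supported;
  the lengthscale is profiled on a grid, never jointly optimized, which
  bounds the LLR from below and avoids multimodal optimization.
- The training engine is single-threaded NumPy: ideal up to a few thousand
  cells and a few hundred features, not intended for atlas-scale data.
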