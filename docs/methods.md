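# Methods

## Problem setting

Replicated multi-location crop trials confound three sources of image
variation: genetics (which hybrid is in the plot), the macro-environment
(the trial location — weather, soil, management), and the
micro-environment (plot-local conditions that make two replicates of the
same hybrid at the same location differ). `phenocae` learns a latent
representation of plot-level multispectral chips in which these three
factors occupy separate, mutually decorrelated blocks, and evaluates the
representation on environment clustering and grain-yield prediction.

## The compositional autoencoder

The unit of processing is a *genotype group*: the N = E·R chips of one
genotype across E locations and R replicates, ordered environment-major.
Each flattened chip (W·H·C = 1452 values in [0, 1] after preprocessing)
passes through a shared encoder

    input → 2200 → 2000 → 1000 → zg + ze + zp     (SELU hidden, linear out)

The N encodings are concatenated and mapped by a single affine *fusion*
layer to a partitioned vector of width `zg + E·ze + N·zp`:

    [ Zg | Ze_1 … Ze_E | Zp_1 … Zp_N ]

Image at group position j (environment e = ⌊j/R⌋) is then represented by
the triple (Zg, Ze_e, Zp_j) — genotype features are shared by the whole
group and macro-environment features by the replicates of one location,
*by construction*, not merely by regularization. The triple is decoded by
a shared decoder

    zg + ze + zp → 2024 → 3000 → 2200 → input     (SELU hidden, sigmoid out)

whose sigmoid output matches the [0, 1] range of the preprocessed chips.
The decoder's first hidden width (2024) is deliberately asymmetric to the
encoder. The vanilla autoencoder baseline uses the identical encoder and
decoder with no fusion; its latent width equals `zg + ze + zp` so the two
representations have equal capacity per image.

The default latent split is 6-6-1 (zg-ze-zp). A dimension sweep utility
(`sweep_latent_configs`) retrains and re-evaluates per configuration.

### Objective

Training minimizes `MSE(x, x̂) + λ · corr_loss`, where the correlation
loss over a batch's per-image latent matrix L (rows = images, columns =
the zg+ze+zp dimensions) is

    corr_loss = Σ_{i≤j} ( |CorrMat_ij| − I_ij ) = Σ_{i<j} |r_ij|,

the sum of absolute Pearson correlations over unique dimension pairs.
Diagonal terms cancel against the identity, so only cross-dimension
correlation is penalized; the loss is bounded by D(D−1)/2. An alternative
mode (`corr_mode="fused"`) decorrelates the full fused vector across
groups instead; the per-image mode is the default because the per-image
triple is what downstream models consume.

The loss participates in gradients. The gradient path uses ε-guarded
denominators (ε = 1e-8) so zero-variance latent dimensions — common at
initialization — produce r = 0 and a zero gradient rather than NaNs; the
*reported* loss uses exact normalization with an explicit zero-variance
branch, which keeps it within ~1e-12 per pair of a brute-force pairwise
Pearson computation.

### Numerical core and optimization

The networks are dense stacks written directly in numpy (closed-form
backward passes, verified against central finite differences to ~1e-6 in
float64). Weights use fan-in-scaled Gaussian initialization, the standard
choice for self-normalizing (SELU) networks; all randomness flows through
seeded `numpy.random.Generator` instances, making runs bit-reproducible
on a fixed platform. The optimizer is Adam with preallocated scratch
buffers (steps over the ~25 M-parameter stack are memory-bandwidth bound,
so the update allocates nothing).

Defaults: learning rate 1e-4, λ = 1.0, 200 epochs, batches of 8 genotype
groups, all recorded in checkpoints. Learning rates near 1e-3 destabilize
reconstruction on the synthetic fixture; 1e-4 descends reliably.

## Preprocessing

Per spectral channel, over *all* plots of one timepoint pooled (channel
value distributions are a dataset-level property; per-image scaling would
destroy cross-plot comparability — a per-image mode exists behind a
flag):

1. clip to mean ± 3·sd (population sd, ddof = 0; the convention is
   recorded in `ChannelStats`);
2. re-estimate min/max, then min–max scale to [0, 1]; a constant channel
   maps to 0;
3. flatten to a W·H·C vector in fixed row-major (W, H, C) order with the
   channel axis fastest; the order is invertible (`unflatten`) and stable
   across save/load.

Timepoints are processed independently: one model per acquisition date.

## Vegetation-index baseline

Thirteen standard indices (GLI, NGRDI, VARI, VEG, RGBVI, ExG, ExR, NDVI,
GNDVI, EVI, SAVI, NDRE, RDVI) are computed per pixel and averaged over
the plot. Committed conventions (the aggregation order and coefficient
sets must be fixed for reproducibility): per-pixel-then-mean; EVI with
G = 2.5, C1 = 6, C2 = 7.5, L = 1; SAVI as 1.5(N−R)/(N+R+0.5); VEG with
a = 0.667; ExG/ExR on chromatic coordinates; all denominators guarded by
ε = 1e-12. Indices are evaluated on clipped but *not* min-max-normalized
reflectance, because min–max scaling is an affine per-channel map that
distorts ratio indices.

## Evaluation protocols

**Disentanglement.** Features are projected to the first three principal
components (centered PCA, deterministic sign convention: each component's
largest-magnitude loading is positive) and scored with the Euclidean
silhouette, singleton clusters contributing s = 0. Macro-environment:
the Ze block against location labels (default), or the full latent with
Zg/Zp mean-imputed (`mode="mean_imputed"`). Micro-environment: the Zp
block against location × replicate labels. The comparator is the same
PCA+silhouette pipeline on raw flattened pixels. Silhouettes are computed
on the 3 PCA coordinates to match the visual protocol; a full-dimension
mode exists behind a flag.

**Yield prediction.** Yields recorded in bu/ac (15.5% moisture, 56 lb/bu)
are converted to t/ha (factor 56 × 0.45359237 / 4046.8564 × 10 ≈ 0.06277)
before cross-validated scoring. Three protocols:

1. *Grouped k-fold CV*: folds partition genotypes (seeded shuffle, fold
   sizes within one genotype), so scores measure prediction for unseen
   genotypes in seen environments. R² is the coefficient of determination
   (can be negative out of sample); RMSE is in t/ha.
2. *Leave-one-location-out rank overlap*: train on all other locations,
   predict the held-out one, average replicates per genotype within the
   location (rankings are of genotypes, not plots), and report
   100·|top_f(true) ∩ top_f(pred)| / |top_f(true)| with
   |top_f| = round(f·G), ties broken by descending value then genotype id.
3. *Unseen environment*: one location never enters the supervised
   training rows; RMSE is reported in the input yield unit. The
   representation model may legitimately be fit unsupervised on all
   imagery including the held-out location.

The regressor is pluggable; the default is gradient-boosted trees
(XGBoost; 800 trees of depth 2, learning rate 0.05, subsample 0.9,
`tree_method="hist"`, single-threaded, fixed seed). Shallow slow
boosting is the right shape for the smooth, near-additive genotype +
location + G×E yield surfaces of small replicated trials — deep trees
memorize training genotypes and generalize worse to held-out ones, on
learned latents and on the generator's true factors alike.

## Synthetic data generator

The generator emulates a replicated hybrid trial imaged once: defaults of
84 genotypes × 5 locations × 2 replicates, 11×22×6 chips with 12-bit
counts. Factors: genotype vectors g ~ N(0, I_dg); location vectors placed
on a sphere of radius `env_separation` (one dial controls location
separability); per-plot micro vectors ~ N(0, micro_sd²). A fixed random
linear map mixes [g; e; p] into pixel space, a low-frequency 2-D cosine
pattern adds spatial structure, and a logistic squash bounds the response
before scaling to [0, 4095], rounding, Gaussian sensor noise, and
re-clipping — so pixel values are integer DNs in the 12-bit range, as
real sensors deliver.

Yield (bu/ac) is `base + w_g·g + w_e·e + gxe·(gᵀMe) + noise` — additive
genotype and location effects, a bilinear G×E interaction, and plot
noise. Default effect scales are chosen to resemble a maize hybrid trial:
base 180 bu/ac, genotype sd 20 bu/ac, location coefficient 12 bu/ac per
unit of environment coordinate, G×E weight 8, plot noise sd 8 bu/ac;
latent dimensions (dg, de, dp) = (6, 6, 2); `env_separation` = 2 makes
locations clearly but not trivially separable (the raw-pixel silhouette
on the reference study is ~0.35, far from saturated). A sequential
regression of simulated yields on the true factors recovers the
configured genotype-effect and noise variances to within ~20–25%
(tested).

What the generator does *not* emulate: radiative-transfer physics,
weather/soil covariates, canopy phenology (one timepoint per dataset),
spatial field trends across plots, or heteroscedastic sensor noise.
Passing tests on this generator therefore demonstrate that the machinery
recovers planted linear-Gaussian factor structure — not that it would
disentangle real satellite imagery, whose factors are neither linear nor
independent.

## Reference study and scale choices

The in-package reference study (`phenocae.study`) runs the full method at
60 genotypes × 5 × 2 (600 chips), 6-6-1 latents, 200 epochs, batches of
10 groups, learning rate 1e-4, λ = 0.2 — sizes chosen so a single CPU
completes the study in minutes. The reduced λ balances the reconstruction
MSE against the pair-sum correlation term (78 pairs at D = 13): with λ
large the decorrelation term dominates and the genotype block retains
less of the yield-relevant signal; λ ≈ 0.2 trains both terms (final
reconstruction MSE < 0.01 on the fixture).

Two structural observations worth knowing when reading its results:

* Part of the Ze separation is architectural: each location reads its own
  fused-vector slot, so even an untrained fusion separates locations to
  some degree. The comparison against the raw-pixel baseline measures the
  representation as the protocol defines it, trained weights and
  architecture together.
* The genotype-grouped CV ceiling is set by how well a tree ensemble
  generalizes a linear genotype effect across hybrids: on this fixture a
  regressor given the *true* factors reaches mean R² ≈ 0.78, so learned
  [Zg | Ze] scores in the 0.6s recover most of what the regressor can
  extract at all.

## Degenerate inputs and tie-breaks

* Zero-variance channel: clipping leaves it unchanged; normalization maps
  it to 0.
* Zero-variance latent dimension: Pearson r defined as 0 (loss and
  gradient).
* All-identical points in the silhouette: score 0 (a ≥ b degenerate
  convention); zero-variance PCA input raises.
* Incomplete genotype groups (missing plots) are dropped from CAE
  training — the fusion layer needs a fixed N — and logged; a
  one-replicate layout (R = 1, N = E) is supported.
* Ranking ties: stable order, descending value then genotype id.

## Known limitations

* Training is single-CPU numpy; wall-clock is minutes at the reference
  scale, not suitable for large imagery archives.
* Checkpoints store raw weight arrays plus a JSON header (versioned), not
  a framework-interchange format.
* The fusion layer is a dense affine map, so replicate-permutation
  equivariance is learned, not guaranteed; only the Zg/Ze sharing across
  a group is structural.
* GeoTIFF georeferencing tags are not preserved; chips are read/written
  as plain multi-band TIFF with band order and plot identity in the
  description tag.
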