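# Methods

## Pipeline

A subject enters as either a parcellated time-series matrix (T × 360) or a
precomputed 360 × 360 connectivity matrix. Pearson correlations between
parcel time series are Fisher z-transformed (`z = atanh(r)`, |r| clipped at
1 − 1e−7 so z stays finite; the diagonal is set to 0 before
sparsification). Optional global signal regression replaces each parcel's
series by its residual on the spatial mean series before correlation.

The connectome splits into four 180 × 180 hemispheric blocks (LL, LR, RL,
RR), with rows and columns reindexed to homolog-pair order so index *i*
denotes the same left/right pair in every block. Per block:

1. **Row sparsification** keeps the top ⌈0.10 · 180⌉ = 18 values per row
   (ties broken toward the lower column index); retained values are
   unchanged.
2. **Affinity**: normalized-angle cosine similarity between sparsified
   rows, `a = 1 − arccos(clip(ρ, −1, 1))/π`, unit diagonal, floored at 0.
3. **Diffusion map** with anisotropy α = 0.5: degrees d, W′ = D^−α W D^−α,
   row-normalized to a Markov operator, eigendecomposed through its
   symmetric conjugate. The trivial stationary eigenvector is dropped; the
   next k = 10 eigenvectors (unit-normalized, then scaled so the stationary
   column is the constant 1) are the gradients, scaled by λ/(1 − λ)
   (diffusion time 0, multiscale). `variance_explained` reports each
   eigenvalue's share of the non-trivial spectrum magnitude.
4. **Alignment**: columns are unit-normalized, then rotated onto the
   reference template by the orthogonal Procrustes solution
   R = UVᵀ of sourceᵀ·template (no scaling/translation). Normalizing
   before the rotation-only fit matters: the multiscale scaling makes G1's
   norm dominate and would otherwise control the rotation. Consequence:
   alignment is exactly invariant to the eigen-decomposition's true
   indeterminacy (column signs and order) but only approximately to
   arbitrary rotations of the component basis.

Alignment happens in the full 10-dimensional space; G1–G3 are read off
afterwards. The asymmetry index is the non-normalized difference
`AI = left − right` per pair and gradient (intra from LL/RR, inter from
LR/RL); a ratio index is unusable because gradient values take both signs.

## Harmonization

Parametric empirical-Bayes location/scale harmonization (the classic
formulation): features standardized with a batch-proportion-weighted grand
mean and pooled variance, covariate structure (age; optionally FIQ and
motion) retained; per-batch locations get a normal prior and squared
scales an inverse-gamma prior, both moment-matched across features and
solved by the standard fixed-point iteration (tolerance 1e−4). The
implementation agrees with the Bioconductor reference to ~1e−14 on shared
input. Two properties of the formulation worth knowing:

* Shrinkage leaves a residual batch-mean difference bounded by the spread
  of per-feature effects; `eb=False` (raw location/scale removal) is exact
  and idempotent when that is needed.
* Variance pooling uses n while per-batch scales use n−1, so
  re-harmonizing rescales centered data by exactly √(n/(n−K)); the
  idempotence test accounts for this analytically.

Diagnosis can never be the batch variable or a removed covariate (guarded),
so group signal survives by construction. In prediction, harmonization is
fitted on the training and test splits *separately* (independent fits, not
transform-from-train); a `from_train` mode exists for comparison.

## Statistics

The primary contrast is multivariate: per homolog pair, Hotelling's T² on
the joint (G1, G2, G3) AI vector, converted exactly to F. General designs
(group, age group, group × age group; treatment coding with child and
autism as references) are tested per term by the Hotelling–Lawley trace
with the standard F approximation — exact whenever min(p, q) = 1, hence
identical to the two-sample T² for the group contrast. At min(p, q) = 2
(the interaction) the approximation is mildly anticonservative (null
rejection ≈ 0.06 at α = 0.05; the common alternative approximation behaves
the same), which is why error control for the interaction is assessed as
the per-pair false-positive rate rather than re-tuned.

Multiplicity: BH-FDR (q = 0.05) over the unit family (180 pairs or 12
networks, per pattern); post-hoc per-gradient pooled-variance t tests are
gatekept by the multivariate FDR flag and evaluated at p < 0.05/3. The t
sign convention is NAI minus autism: positive t = lower leftward asymmetry
in autism. Within-group age contrasts compare the three age-group pairs at
Bonferroni p < 0.05/3. A singular pooled covariance falls back to a ridge
(λ = 1e−6 · tr(S)/p) and is flagged. A rank-deficient factorial design
(an empty group × age cell in a small cohort) yields NaN statistics rather
than an error.

Age groups default to child [5, 12), adolescent [12, 18), adult [18, 40]
and are configurable, since reasonable boundary conventions differ.

## Decoding and prediction

Decoding ranks parcels by the statistic map, cuts them into 20 contiguous
rank bins (remainder spread deterministically over the lowest bins, ties
by parcel index), takes each bin's mean statistic as its loading, and
scores a term map as Σ_bins mean(z > 0 within bin) × loading. Negative
loadings contribute signed (an absolute-value mode exists); "loading =
mean t of the bin" is the central interpretive choice of this module.

Prediction uses 540 features (180 pairs × 3 gradients, one pattern).
Each permutation: a random 4:1 split stratified by site (so each split
keeps ≥ 2 subjects per site, which per-split harmonization requires);
site effects removed and age residualized out in each split independently;
features z-scored with training-split statistics; elastic net at
l1_ratio = 0.1 over 30 log-spaced alphas on [1e−4, 1] (only the endpoints
are canonical; 30 points is this package's grid), chosen by 5-fold CV MAE
(contiguous folds of a seeded shuffle, warm-started descending alpha path)
and refitted on the full training split. Reported: train/test MAE, test
Pearson r, and non-zero-coefficient selection frequency across
permutations, aggregable to network × gradient.

## The synthetic cohort generator

The generator is the study's ground-truth instrument, not a fixture. A
cohort has two balanced diagnostic groups across 5 sites, ages uniform on
5–40, FIQ ~ N(110, 12) with a −8 offset in the autism group, and mean
framewise displacement ~ |N(0.10, 0.05)| with a +0.02 autism offset,
mirroring typical cohort differences. Exclusion rules (age > 40, FIQ < 70,
FD > 0.3 mm) flag rows without dropping them.

**Connectome route.** Each hemisphere carries per-parcel scores on k = 3
latent axes with decreasing weights (1, 0.6, 0.35); a block's Fisher-z
matrix is `18 · U_a diag(w) U_bᵀ + 0.25` (inner products squashed through
tanh to (−1, 1) and re-expanded by the downstream atanh — the two compose
to the identity, so the constants act directly on z) plus symmetric edge
noise; site effects are location/scale changes on the z values. Planted
effects are opposite-signed shifts on the left and right homolog (half
each) in fixed AI units (`LATENT_AI_SD = 0.03`), so they survive a
noise-free run.

The latent template is *calibrated*: an arbitrary smooth axis is generally
not in the image of sparsify → affinity → diffusion map (the best linear
read-out from 10 components tops out near Spearman 0.97), so the generator
iterates the pipeline to a reproducing fixed point — embed the noise-free
block, align back onto the current axes, orthonormalize, repeat, keep the
most self-consistent iterate. Gradients are by construction what the
pipeline measures, so this is the right notion of "planted axis"; aligned
noise-free recovery reaches |Spearman| ≈ 0.98 on the intra blocks. The
cross-hemispheric blocks retain their homotopic diagonal and recover
slightly less cleanly.

**Direct feature route.** For replicate-heavy operating-characteristic
studies, the generator emits AI features directly from the latent model:
baseline asymmetry + group shift (0.8 sd on 10 language-network pairs, G1)
+ group-specific age slopes (NAI 0.15 sd/year, autism 0, G3 pairs) +
between-subject noise with unit marginal variance, half of it shared
low-rank structure (20 common patterns with subject loadings, as in real
asymmetry maps — this also gives the feature matrix a realistic effective
dimensionality for prediction) — then per-site location/scale effects.
Planted standardized effects are exact here; through the full embedding
route they attenuate (a planted 0.8 realizes around 0.3–0.6 per pair),
which is a property of the embedding, not of the statistics under test.
The interaction slope (0.15 sd/year) is chosen so that FDR-gated detection
over 180 pairs has high power with ~14 children per group; the
group-difference magnitude (0.8 sd) matches the replicate-study design.

ADOS scores are a sparse linear function of the *true* (site-effect-free)
intra-hemispheric AI features plus Gaussian noise calibrated to a
generating R² of 0.3, then shifted/scaled to a plausible range, rounded,
and clipped at 0; communication and social subscores share the signal, RRB
is pure noise. Term maps for decoding are smooth random fields with an
optional planted term equal to the positive part of a supplied map.

Everything is driven by one seed and regenerates bit-identically.

**What the generator does not emulate:** hemodynamics, motion artifacts,
spatial autocorrelation on a cortical surface, non-Gaussian site effects,
heavy-tailed trait distributions, or diagnosis–site confounding. Passing
tests therefore demonstrate that the machinery is correct and calibrated
under its stated model, not that effects of these sizes exist in real
cohorts.

A caveat on null prediction runs: across cohorts the expected test r is
zero, but within one cohort cross-validation consistently exploits that
cohort's chance correlations between the trait and the shared noise
factors, so a single null cohort's mean test r can sit anywhere within
roughly ±0.2. Null behavior is therefore a statement about the procedure
in expectation, assessed at the designed study conditions.

## Problem sizes and numerical choices

Replicate studies use 50 synthetic cohorts of n = 70 per group; the
Hotelling null calibration uses 2000 draws; permutation agreement uses
10,000 label permutations on 20 fixed datasets; prediction studies use 25
permutations at n = 150. Dense eigendecompositions (180 × 180) are exact
(`numpy.linalg.eigh`); embedding sign indeterminacy is fixed by making the
largest-magnitude entry positive, and alignment resolves the rest. CSV
writers use a fixed float format so repeated runs are byte-identical.

## Known limitations

* The similarity (idiosyncrasy) score is a plain mean Pearson correlation
  with same-site peers; alternative reference populations are options, and
  the score is validated only against its own oracle.
* Network-level inference treats networks as fixed, disjoint parcel sets;
  no spatial or surface-based correction is attempted.
* The prediction stage's literal per-split harmonization trades a known
  covariate-shift cost for strict split independence; the
  transform-from-train alternative is provided but not the default.
* Heritability values are external inputs in the original analysis and are
  out of scope here.
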