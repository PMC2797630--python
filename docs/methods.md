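# Methods

This note documents the models and procedures implemented in
`neurofactor`, the numerical choices behind them, what the synthetic data
generator does and does not emulate, and the known limitations.

## Data model

The unit of analysis is a words × voxels activation matrix per participant
and presentation: one mean, preprocessed image per word presentation, on a
regular 3-D grid of anisotropic voxels (default 3.125 × 3.125 × 6 mm)
partitioned into five bilateral "lobes" (frontal, parietal, temporal,
occipital, and a fusiform/parahippocampal lobe kept separate because of its
prominence in object representation). The package starts from these
word-level images; hemodynamic time series, percent-signal-change
computation and spatial normalisation are upstream of its scope.

All standard deviations use the sample convention (denominator n − 1).
Voxel grid indices are 0-based; mm coordinate = origin + index × voxel
size.

## Stability screening

A voxel's stability is the mean Pearson correlation between its word
activation profiles over all unordered pairs of presentations. It is a
reliability screen: only voxels that respond to the word set consistently
can carry information downstream. In cross-participant scope, each training
participant's mean profile acts as one "presentation" and stability is the
mean pairwise correlation across participants. Ranking ties are broken by
ascending voxel id so selection is deterministic. A constant profile makes
the correlation undefined; the low-level function raises by default, while
the pipeline entry points score such voxels 0 (maximally unstable), which
keeps the noise-free limit — where background voxels are exactly constant —
well defined without affecting any informative voxel.

## Two-level factor analysis

First level, per participant and lobe: the correlation matrix of the 50
most stable voxels' normalized mean profiles is factored by iterated
principal axis factoring (PAF) and the five retained factors are varimax
rotated. Factor profiles (factor scores per word) are recovered by
ordinary least squares from the loadings. Second level: the pooled
first-level profiles (participants × lobes × 5) are standardized,
correlated, and factored the same way with ten factors — a higher-order
factor analysis that finds dimensions shared across lobes and
participants.

PAF numerics: initial communalities are squared multiple correlations
(via pseudo-inverse, clipped to [0, 0.995]); each iteration
eigendecomposes the reduced correlation matrix, clamps negative
eigenvalues at zero, forms loadings from the top-k eigenpairs, and updates
communalities (capped at 1). Convergence is a maximum communality change
below 1e-3 — the convergence default of the classical SAS implementation
of this procedure — within at most 1000 iterations. The generous iteration
ceiling matters in small-item configurations (e.g. ten factors from 25
first-level profiles) where communalities approach their unit bound
slowly; non-convergence raises an error carrying the change trace rather
than returning a half-converged answer. When the input is exactly rank
deficient (noise-free synthetic data), factors with zero eigenvalue are
dropped: they carry all-zero loadings and would otherwise poison the
least-squares profile solve, which by contract refuses rank-deficient
loading matrices.

Varimax uses Kaiser row normalisation and classical pairwise planar
sweeps: for every factor pair the rotation angle maximising the pair's
criterion has a closed form (a four-quadrant arctangent), so each step is
a global planar ascent and perfectly balanced loading patterns — which are
stationary points of gradient-projection variants — cannot stall it.
Sweeps stop when the relative criterion gain falls below 1e-6. Rotated
factors are ordered by explained sum of squares and sign-flipped so the
dominant loading is positive; together with the tie rules this makes the
whole pipeline deterministic. Factor profiles are identified only up to
order and sign, so all recovery checks align factors to references by
Hungarian assignment on absolute correlation.

Assignment and commonality: an item (voxel at level 1, first-level factor
at level 2) belongs to its highest-|loading| factor when that loading is
at least 0.4, a conventional exploratory threshold; composing the two
mappings assigns voxels to second-level factors. A second-level factor's
commonality is the number of participants contributing assigned voxels;
its explained-variation share is the sum of its squared loadings divided
by the number of items. The "common factors" used downstream are the
top-n (default 4) by commonality, then variance share, then index.

A single-level variant (one factor analysis of all participants' stable
voxels pooled, skipping the per-lobe level) is provided as a robustness
check; on planted data its leading factors agree with the two-level
scores.

## Localization

Voxels assigned to a factor are clustered as connected components
(26-neighbourhood by default; 6 and 18 available) with a minimum size of
five voxels, pooling assignments over participants (a shared coordinate
frame is assumed). Each cluster is summarised by the centroid of its
member voxel centres in mm and a radius equal to the members' mean
Euclidean distance from the centroid (mean radial dispersion); physical
coordinates handle anisotropic voxels. For feature selection each sphere
becomes a cuboid search volume: the sphere's voxel-index bounding box
grown by one voxel per dimension and clipped at the grid edge — cheap to
test membership against and slightly permissive by construction.

## Decoding

Factor-based feature selection takes, inside each search volume, the
voxels with the highest product of (a) |Pearson correlation| between the
voxel's mean training profile and the volume's factor profile and (b) the
voxel's training-set stability; the absolute value is the default because
rotated factors carry arbitrary sign (a signed mode exists). Five voxels
per volume over 16 volumes gives the standard 80-feature set;
stability-only selection (top 80 anywhere in cortex) is the baseline, and
single-factor or three-semantic-factor variants restrict the volumes.
Selection sees training data only; guard tests verify that perturbing
held-out presentations or held-out participants never changes the feature
set, and that factor contexts are always built from other participants'
analyses.

The classifier is Gaussian Naive Bayes with pooled variance: per-class
feature means, and a single per-feature variance estimated as the sample
variance of class-mean-centred values pooled over all classes. Posteriors
are computed in log space; exact ties break by word order. Pipelines floor
the pooled variance at 1e-12 so the noise-free limit (zero within-class
variance) degenerates gracefully into nearest-mean classification; the
low-level fit raises on zero variance by default. Performance is the
normalized rank accuracy (N − r)/(N − 1) of the correct label in the
posterior-ordered list, 0.50 at chance for any N.

Within-participant cross-validation enumerates all C(6,2) = 15 ways of
leaving two presentations out: stability and feature selection are redone
from the four training presentations, training and test activations are
z-scored across words separately (per voxel), and the classifier is tested
on the mean image of the two left-out presentations. Cross-participant
cross-validation leaves one participant out: each training participant's
six-presentation mean image per word is one training example, and the
factor context for a test participant comes from the other participants
only. Within-category identification re-ranks the correct word among its
own category's five members, with a random-five-candidates control.

Permutation thresholds rerun the full cross-validation with training
labels permuted (one permutation per run, test labels fixed) and take the
empirical (1 − α) quantile of the permuted mean accuracies.

## Generative prediction

For each of the C(60,2) = 1,770 word pairs (or a seeded subsample), the
factor pipeline is rerun on the remaining 58 words, search volumes and the
80-voxel feature set are re-derived, and an independent OLS regression per
voxel maps semantic predictors to activation. Training predictors are, by
default, the fold's second-level factor scores over the 58 words, matched
to the rating dimensions (three semantic scales plus word length) by
Hungarian assignment on absolute correlation and sign-aligned; a
"ratings" mode uses the ratings on both sides and is the exact limit when
activation is linear in the rated dimensions. Test predictors are always
the held-out words' ratings, z-scored against the 58 training words'
ratings so train and test predictors live on a common scale. Activations
are z-scored per voxel using training-word statistics only, so held-out
words never leak into the normalisation. The two predicted images are
matched to the two observed images by total cosine similarity; exact ties
count as incorrect (conservative). Chance is assessed by the exact
binomial tail: the threshold is the smallest k/n with
P(X ≥ k | n, 1/2) ≤ α, which is 0.537 for n = 1,770 at α = .001. If a fold
yields no localizable cluster at all (this happens only on signal-free
data), selection falls back to the top-80 stable voxels so the null
behaviour of the protocol remains measurable.

The cross-participant generative variant trains the regression on the
other participants' mean images for the 58 words and matches the held-out
participant's two images; the held-out participant contributes nothing to
the factor analysis, selection or fit.

## Synthetic data generator

The generator is the package's test bed and defines its study conditions.
Defaults: 4 participants × 6 presentations × 60 words (the built-in
12-category noun set) on a 10 × 10 × 15 grid (1,500 voxels) of
3.125 × 3.125 × 6 mm voxels, five equal lobe slabs along z. Four latent
factors — three semantic profiles built as category-weight mixtures with
per-word jitter (SD 0.3) and one profile equal to the z-scored letter
count — are each expressed in four spherical clusters of radius 1.5 voxel
indices (19 voxels), placed so every factor spans four lobes, every lobe
hosts three or four factors, and no two clusters touch: 16 clusters in
total, comparable in size and count to the cluster geometry the method is
expected to find in real data. In-cluster loadings are uniform in
[0.8, 1.2]; profiles are z-scored, so the per-voxel signal SD is ~1 and
the default per-presentation noise SD of 0.3 reads directly as a
noise-to-signal fraction. Participants share loadings and profiles (a
common neural code) up to a scalar gain with SD 0.1. Two switches create
contrast regimes: `signal_scale=0` yields pure-noise null data, and
`shared_code=False` passes each participant's loading matrix through its
own seeded voxel permutation — the code remains decodable within a
participant but its spatial layout is idiosyncratic, which collapses
cross-participant transfer to chance while leaving within-participant
accuracy intact. Ratings tables are affine rescalings of the true semantic
profiles into [1, 7] plus truncated Gaussian noise. Profile jitter is
keyed to the word string, so permuting the word order permutes the planted
structure identically.

What the generator does **not** emulate: hemodynamics and temporal
structure, spatially correlated or heteroscedastic noise, per-participant
anatomical variability or misregistration, partial-volume and draining-vein
effects, non-spherical or overlapping factor territories, and
activation that is non-linear in the semantic dimensions. Passing tests
therefore demonstrate that the algorithms are implemented correctly and
recover planted structure under the stated noise model — not that real
fMRI data satisfy that model.

## Problem sizes used in the shipped checks

The test suite and the acceptance script run at the canonical
configuration (4 participants, 1,500 voxels, noise 0.3) for factor and
cluster recovery; decoding sanity checks use single-participant noise-free
and signal-free datasets; generative checks use seeded subsamples of the
1,770 pairs (100 for the noiseless and default-noise runs, 30–50 for null
and noise-sweep runs), with the full enumeration available through the
API and CLI. These sizes were chosen as the smallest at which every
qualitative contrast (perfect/chance/collapsed) is unambiguous.

## Known limitations

- The 0.4 assignment threshold, 50-voxel and 80-feature counts are
  conventions inherited from the method being implemented, not quantities
  the package re-optimises.
- PAF communality estimation can be slow near Heywood cases; the
  implementation caps communalities at 1 and bounds iterations rather than
  regularising, to stay faithful to the classical procedure.
- Commonality counts participants via thresholded assignments and is
  therefore sensitive to the 0.4 threshold in marginal cases.
- The generative model is linear per voxel; interactions between semantic
  dimensions are not modelled.
- LSA-style similarity vectors and word frequencies are accepted as
  externally supplied per-word tables; the package does not compute them
  from corpora.
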