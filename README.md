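# neurofactor

Latent semantic factor analysis and decoding of word-evoked voxel
activation, with a ground-truth synthetic data generator.

## The problem

When a person reads a concrete noun like *apple* and thinks about the
object, the evoked fMRI activation pattern carries information about the
word's meaning. A productive way to study that code is to (1) screen voxels
for *stability* — reproducibility of their 60-word response profile across
repeated presentations — (2) factor the stable voxels' activation profiles
to discover a small set of latent semantic dimensions (e.g. *shelter*,
*manipulation*, *eating*, plus a perceptual *word length* dimension),
(3) trace each factor back to a handful of compact cortical clusters, and
(4) test the account with machine-learning protocols: rank-accuracy word
identification within and across participants, and zero-shot prediction of
activation for words the model has never seen.

`neurofactor` implements that full pipeline for anyone who wants to study,
extend or stress-test these methods. Because word-level fMRI datasets of
this design are rarely shareable, the package ships a first-class synthetic
data generator that plants a known factor structure (profiles, loadings,
cluster geometry) on a labelled voxel grid, so every stage can be validated
against ground truth.

## The model

Each voxel's 60-word mean activation profile v_i is modelled as a linear
combination of first-level factor profiles F_j (principal axis factoring
with varimax rotation on the correlation matrix of the 50 most stable
voxels per lobe per participant):

    v_i = Σ_j c_ij F_j ,  j = 1…5

A second-level (higher-order) factor analysis models the pooled first-level
profiles as combinations of dimensions common across lobes and
participants:

    F_n = Σ_k d_nk G_k ,  k = 1…10

Profiles are recovered from loadings by least squares; items are assigned
to their highest-|loading| factor above 0.4; a factor's *commonality* is
the number of participants whose voxels map to it. Factor voxels are
clustered (≥ 5 connected voxels), summarised by centroid/mean-radial-
dispersion spheres, and widened into cuboid search volumes from which 5
voxels per volume (16 volumes → 80 features) are chosen by the product of
factor-profile correlation and stability. Identification uses a Gaussian
Naive Bayes classifier with pooled per-feature variance and reports the
normalized rank accuracy (N − r)/(N − 1), which is 0.50 at chance. The
generative stage regresses each selected voxel's activation on semantic
predictors over 58 words and predicts the held-out pair from behavioural
ratings, matching predicted to observed images by cosine similarity over
all C(60,2) = 1,770 pairs, against an exact binomial chance threshold
(0.537 at p < .001 for 1,770 trials).

## Worked example

```python
import neurofactor as nf
from neurofactor.decoding import (FeaturePolicy, build_factor_context,
                                  select_common_factors, within_participant_cv)

words = nf.builtin_wordset()
config = nf.SyntheticConfig(seed=1)           # 4 participants, 16 planted clusters
dataset, truth = nf.generate_dataset(config, words)

model = nf.run_two_level(dataset)             # 20 first-level FAs -> 1 second-level FA
common = select_common_factors(model, 4)
matched, signs, abs_r = nf.align_factors(
    model.second_level.profiles[list(common)], truth.factor_profiles
)
for k, name in enumerate(truth.factor_names):
    print(f"{name:>12}: |r| = {abs_r[k]:.3f}, commonality "
          f"{model.commonality[common[matched[k]]]}/4")

locations = nf.localize_factors(model, dataset, factors=common)
print("clusters recovered:", sum(len(v) for v in locations.values()))

context = build_factor_context(dataset, [1, 2, 3])   # never participant 0
result = within_participant_cv(dataset, 0, FeaturePolicy(mode="factor"),
                               context=context)
print(f"mean rank accuracy (participant 0): {result.mean_accuracy:.3f}")
```

Output:

```
     shelter: |r| = 0.980, commonality 4/4
manipulation: |r| = 0.966, commonality 4/4
      eating: |r| = 0.991, commonality 4/4
 word_length: |r| = 0.986, commonality 4/4
clusters recovered: 16
mean rank accuracy (participant 0): 1.000
```

All four planted dimensions are recovered with |r| ≈ 0.97–0.99 and are
common to all four synthetic participants; all 16 planted clusters are
found; and an 80-voxel feature set selected with factor locations from the
*other* participants decodes participant 0's words perfectly at the default
noise level (per-presentation noise SD = 0.3 × signal SD).

A command-line interface mirrors the library
(`neurofactor simulate|stability|factors|localize|decode|predict|validate|report`),
e.g.:

```bash
neurofactor simulate --out runs/demo --seed 1
neurofactor factors --data runs/demo --out runs/demo/fa
```

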