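"""Word identification from voxel activation patterns.

Feature selection (factor-based or stability-only), a Gaussian Naive Bayes
classifier with pooled per-feature variance, normalized rank accuracy, and
the within-participant (leave-two-presentations-out) and cross-participant
(leave-one-participant-out) cross-validation protocols, plus permutation
thresholds.

The classifier models P(X | Y=y) as a product of per-feature Gaussians
whose means are class specific but whose variance is pooled across classes
(sample variance of the class-mean-centred values). Identification quality
is reported as the normalized rank of the correct label in the
posterior-ordered candidate list, (N - r) / (N - 1), whose chance level is
0.50 for any N.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Callable, Literal, Sequence

import numpy as np

from .dataset import ActivationDataset
from .factors import TwoLevelFactorModel, run_two_level
from .localization import SearchVolume, localize_factors, make_search_volume
from .preprocess import voxel_stability
from .words import WordSet

__all__ = [
    "GNBModel",
    "DecodingResult",
    "FeaturePolicy",
    "FactorContext",
    "semantic_stability_score",
    "select_features",
    "gnb_fit",
    "gnb_rank",
    "rank_accuracy",
    "within_participant_cv",
    "within_category_accuracy",
    "random_candidate_accuracy",
    "cross_participant_cv",
    "permutation_threshold",
    "build_factor_context",
    "select_common_factors",
]


# ----------------------------------------------------------------------
# scoring and feature selection


def semantic_stability_score(
    voxel_profile: np.ndarray,
    factor_profile: np.ndarray,
    stability: float,
    corr_mode: Literal["abs", "signed"] = "abs",
) -> float:
    """Product of a voxel's profile-to-factor correlation and its stability.

    Factor profiles carry arbitrary sign after rotation, so by default the
    absolute correlation is used; ``corr_mode="signed"`` keeps the raw sign.
    """
    v = np.asarray(voxel_profile, dtype=float)
    f = np.asarray(factor_profile, dtype=float)
    if v.shape != f.shape:
        raise ValueError("profiles must have the same length")
    if v.std() == 0 or f.std() == 0:
        raise ValueError("constant profile: correlation undefined")
    r = float(np.corrcoef(v, f)[0, 1])
    if corr_mode == "abs":
        r = abs(r)
    return r * float(stability)


def _profile_factor_corr(profiles: np.ndarray, factor_profile: np.ndarray) -> np.ndarray:
    """Correlation of each row with the factor profile; degenerate rows -> 0."""
    f = factor_profile - factor_profile.mean()
    fn = np.linalg.norm(f)
    centred = profiles - profiles.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(centred, axis=1)
    safe = np.where(norms > 0, norms, 1.0)
    r = (centred @ f) / (safe * fn)
    return np.where(norms > 0, r, 0.0)


@dataclass
class FactorContext:
    """Search volumes and factor profiles used for factor-based selection.

    Built from factor analyses of participants *other than* the one being
    decoded, so selection never leans on the test participant's own factor
    structure.
    """

    volumes: list[SearchVolume]
    factor_profiles: dict[int, np.ndarray]
    factor_names: dict[int, str] = field(default_factory=dict)
    source_participants: tuple[int, ...] = ()


@dataclass(frozen=True)
class FeaturePolicy:
    """How voxels are chosen for the classifier.

    mode "factor": ``per_volume`` voxels per search volume, highest product
    of semantic and stability scores; "stability": the ``n_features`` most
    stable voxels anywhere in cortex. ``factors`` restricts factor-based
    selection to a subset (single-factor or three-semantic-factor variants).
    """

    mode: Literal["factor", "stability"] = "stability"
    n_features: int = 80
    per_volume: int = 5
    factors: tuple[int, ...] | None = None
    corr_mode: Literal["abs", "signed"] = "abs"


@dataclass
class FeatureSet:
    voxel_ids: np.ndarray
    mode: str
    provenance: np.ndarray  # per voxel: factor id, or -1 for stability-only


def select_features(
    dataset: ActivationDataset,
    participants: int | Sequence[int],
    presentations: Sequence[int] | None,
    policy: FeaturePolicy,
    context: FactorContext | None = None,
) -> FeatureSet:
    """Select classifier voxels from training presentations only."""
    stability = voxel_stability(
        dataset, participants, presentations, on_constant="zero"
    )
    if policy.mode == "stability":
        order = np.argsort(-stability, kind="stable")
        ids = order[: policy.n_features]
        return FeatureSet(ids, "stability", np.full(len(ids), -1))
    if context is None:
        raise ValueError("factor-based selection requires a FactorContext")
    if not context.volumes:
        raise ValueError("factor context has no search volumes")
    if np.isscalar(participants):
        mean_prof = dataset.values[int(participants)]
    else:
        mean_prof = dataset.values[list(participants)].mean(axis=0)
    pres = (
        list(presentations)
        if presentations is not None
        else list(range(dataset.n_presentations))
    )
    profiles = mean_prof[pres].mean(axis=0).T  # voxels x words
    ids_out: list[np.ndarray] = []
    prov: list[np.ndarray] = []
    for volume in context.volumes:
        if policy.factors is not None and volume.factor not in policy.factors:
            continue
        cand = volume.voxel_ids(dataset)
        if len(cand) < policy.per_volume:
            raise ValueError(
                f"search volume for factor {volume.factor} holds only "
                f"{len(cand)} voxels; need {policy.per_volume}"
            )
        r = _profile_factor_corr(
            profiles[cand], context.factor_profiles[volume.factor]
        )
        if policy.corr_mode == "abs":
            r = np.abs(r)
        score = r * stability[cand]
        order = np.argsort(-score, kind="stable")
        chosen = cand[order[: policy.per_volume]]
        ids_out.append(chosen)
        prov.append(np.full(len(chosen), volume.factor))
    return FeatureSet(
        np.concatenate(ids_out), policy.mode, np.concatenate(prov)
    )


def select_common_factors(model: TwoLevelFactorModel, n: int = 4) -> tuple[int, ...]:
    """The n second-level factors shared by most participants (ties by
    explained variation, then factor index)."""
    order = sorted(
        range(model.second_level.n_factors),
        key=lambda k: (-model.commonality[k], -model.variance_share[k], k),
    )
    return tuple(order[:n])


def build_factor_context(
    dataset: ActivationDataset,
    participants: Sequence[int],
    n_factors: int = 4,
    min_cluster: int = 5,
    connectivity: int = 26,
    **two_level_kwargs,
) -> FactorContext:
    """Run the two-level pipeline on the given participants and package the
    resulting factor locations as search volumes."""
    model = run_two_level(dataset, participants, **two_level_kwargs)
    common = select_common_factors(model, n_factors)
    locations = localize_factors(
        dataset=dataset,
        model=model,
        factors=common,
        min_size=min_cluster,
        connectivity=connectivity,
    )
    volumes = [
        make_search_volume(loc, dataset)
        for k in common
        for loc in locations[k]
    ]
    profiles = {k: model.second_level.profiles[k] for k in common}
    return FactorContext(
        volumes=volumes,
        factor_profiles=profiles,
        source_participants=tuple(int(p) for p in participants),
    )


# ----------------------------------------------------------------------
# Gaussian Naive Bayes with pooled variance


@dataclass
class GNBModel:
    classes: np.ndarray
    means: np.ndarray
    pooled_var: np.ndarray
    priors: np.ndarray


def gnb_fit(
    X: np.ndarray, y: np.ndarray, var_floor: float = 0.0
) -> GNBModel:
    """Fit class means and a single pooled per-feature variance.

    The pooled variance is the sample variance (denominator n-1) of the
    class-mean-centred values over all training examples. A feature with
    zero pooled variance is an error unless ``var_floor`` > 0, in which case
    variances are floored (used by pipelines to keep the noise-free limit
    well defined).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if X.ndim != 2 or len(y) != X.shape[0]:
        raise ValueError("X must be (examples, features) aligned with y")
    if X.shape[0] < 2:
        raise ValueError("need at least two training examples")
    classes, y_idx = np.unique(y, return_inverse=True)
    means = np.zeros((len(classes), X.shape[1]))
    for c in range(len(classes)):
        means[c] = X[y_idx == c].mean(axis=0)
    centred = X - means[y_idx]
    pooled = (centred**2).sum(axis=0) / (X.shape[0] - 1)
    if var_floor > 0:
        pooled = np.maximum(pooled, var_floor)
    else:
        zero = np.flatnonzero(pooled == 0)
        if zero.size:
            raise ValueError(
                f"zero pooled variance for feature(s) {zero[:5].tolist()}"
            )
    priors = np.bincount(y_idx, minlength=len(classes)) / len(y)
    return GNBModel(classes=classes, means=means, pooled_var=pooled, priors=priors)


def gnb_rank(model: GNBModel, x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Classes ranked by descending posterior for one test vector.

    Computed in log space; exact posterior ties are broken by class order.
    Returns (ranked class labels, log posterior per class in class order).
    """
    x = np.asarray(x, dtype=float)
    if x.shape != (model.means.shape[1],):
        raise ValueError("test vector length does not match the model")
    log_lik = (
        -0.5 * ((x - model.means) ** 2 / model.pooled_var).sum(axis=1)
        - 0.5 * np.log(2 * np.pi * model.pooled_var).sum()
    )
    log_post = log_lik + np.log(model.priors)
    order = np.lexsort((np.arange(len(model.classes)), -log_post))
    return model.classes[order], log_post


def rank_accuracy(rank: int, n_classes: int) -> float:
    """Normalized rank accuracy (N - r) / (N - 1); 1 = top, mean 0.5 at chance."""
    if not 1 <= rank <= n_classes:
        raise ValueError(f"rank {rank} outside [1, {n_classes}]")
    return (n_classes - rank) / (n_classes - 1)


# ----------------------------------------------------------------------
# cross-validation protocols


@dataclass
class DecodingResult:
    """Per-fold ranked lists and rank accuracies.

    ``fold_ranked[f][w]`` is the ranked label list (word indices) for test
    word w in fold f; ``fold_accuracy`` is (folds, words); ``word_accuracy``
    averages over folds and ``mean_accuracy`` over words.
    """

    fold_ranked: list[np.ndarray]
    fold_accuracy: np.ndarray
    feature_sets: list[FeatureSet] = field(default_factory=list)

    @property
    def word_accuracy(self) -> np.ndarray:
        return self.fold_accuracy.mean(axis=0)

    @property
    def mean_accuracy(self) -> float:
        return float(self.word_accuracy.mean())


def _zscore_columns(mat: np.ndarray) -> np.ndarray:
    """Z-score each column (voxel) across rows (words); constant columns pass
    through centred (they carry no ranking information either way)."""
    sd = mat.std(axis=0, ddof=1)
    safe = np.where(sd > 0, sd, 1.0)
    return (mat - mat.mean(axis=0)) / safe


def _rank_of(ranked: np.ndarray, label: int) -> int:
    return int(np.flatnonzero(ranked == label)[0]) + 1


def within_participant_cv(
    dataset: ActivationDataset,
    participant: int,
    policy: FeaturePolicy,
    context: FactorContext | None = None,
    var_floor: float = 1e-12,
    label_permutation: np.ndarray | None = None,
) -> DecodingResult:
    """All C(n_presentations, 2) leave-two-presentations-out folds.

    Per fold, stability and feature selection use the training presentations
    only; training and test activations are normalized across words
    separately; the classifier is tested on the mean image of the two
    left-out presentations of each word. ``label_permutation`` relabels the
    training examples (permutation testing) while test labels stay fixed.
    """
    n_words = dataset.n_words
    labels = np.arange(n_words)
    fold_ranked: list[np.ndarray] = []
    fold_acc: list[np.ndarray] = []
    feature_sets: list[FeatureSet] = []
    all_pres = range(dataset.n_presentations)
    for test_pair in itertools.combinations(all_pres, 2):
        train_pres = [r for r in all_pres if r not in test_pair]
        feats = select_features(dataset, participant, train_pres, policy, context)
        feature_sets.append(feats)
        cols = feats.voxel_ids
        X_train = np.vstack(
            [
                _zscore_columns(dataset.values[participant, r][:, cols])
                for r in train_pres
            ]
        )
        y_train = np.tile(labels, len(train_pres))
        if label_permutation is not None:
            y_train = np.asarray(label_permutation)[y_train]
        model = gnb_fit(X_train, y_train, var_floor=var_floor)
        test_mean = dataset.values[participant, list(test_pair)].mean(axis=0)[:, cols]
        X_test = _zscore_columns(test_mean)
        ranked_fold = np.empty((n_words, n_words), dtype=int)
        acc = np.empty(n_words)
        for w in range(n_words):
            ranked, _ = gnb_rank(model, X_test[w])
            ranked_fold[w] = ranked
            acc[w] = rank_accuracy(_rank_of(ranked, w), n_words)
        fold_ranked.append(ranked_fold)
        fold_acc.append(acc)
    return DecodingResult(
        fold_ranked=fold_ranked,
        fold_accuracy=np.vstack(fold_acc),
        feature_sets=feature_sets,
    )


def within_category_accuracy(result: DecodingResult, wordset: WordSet) -> float:
    """Mean normalized rank of the correct word among its own category's
    five members (classifier trained on all words)."""
    cats = np.asarray(wordset.categories)
    accs = []
    for ranked_fold in result.fold_ranked:
        for w, ranked in enumerate(ranked_fold):
            members = np.flatnonzero(cats == cats[w])
            within = ranked[np.isin(ranked, members)]
            r = _rank_of(within, w)
            accs.append(rank_accuracy(r, len(members)))
    return float(np.mean(accs))


def random_candidate_accuracy(
    result: DecodingResult, n_candidates: int = 5, seed: int = 0
) -> float:
    """Control: rank of the correct word among itself plus random candidates."""
    rng = np.random.default_rng(seed)
    accs = []
    for ranked_fold in result.fold_ranked:
        n_words = ranked_fold.shape[1]
        for w, ranked in enumerate(ranked_fold):
            others = np.delete(np.arange(n_words), w)
            cand = np.concatenate(
                [[w], rng.choice(others, n_candidates - 1, replace=False)]
            )
            within = ranked[np.isin(ranked, cand)]
            accs.append(rank_accuracy(_rank_of(within, w), n_candidates))
    return float(np.mean(accs))


def cross_participant_cv(
    dataset: ActivationDataset,
    policy: FeaturePolicy,
    contexts: dict[int, FactorContext] | None = None,
    participants: Sequence[int] | None = None,
    var_floor: float = 1e-12,
    label_permutation: np.ndarray | None = None,
) -> dict[int, DecodingResult]:
    """Leave-one-participant-out word identification.

    Training examples are each training participant's mean image per word
    (the participant means act as presentations); stability is computed
    across training participants only, and for factor-based selection the
    supplied per-test-participant context must come from analyses excluding
    that participant. The test participant's own data are never touched
    during selection or training.
    """
    if participants is None:
        participants = range(dataset.n_participants)
    participants = [int(p) for p in participants]
    if len(participants) < 2:
        raise ValueError("cross-participant CV needs at least two participants")
    n_words = dataset.n_words
    labels = np.arange(n_words)
    out: dict[int, DecodingResult] = {}
    for test_p in participants:
        train_parts = [p for p in participants if p != test_p]
        context = contexts.get(test_p) if contexts else None
        if context is not None and test_p in context.source_participants:
            raise ValueError(
                f"factor context for participant {test_p} was built from "
                "their own data"
            )
        feats = select_features(dataset, train_parts, None, policy, context)
        cols = feats.voxel_ids
        X_train = np.vstack(
            [
                _zscore_columns(dataset.values[p].mean(axis=0)[:, cols])
                for p in train_parts
            ]
        )
        y_train = np.tile(labels, len(train_parts))
        if label_permutation is not None:
            y_train = np.asarray(label_permutation)[y_train]
        model = gnb_fit(X_train, y_train, var_floor=var_floor)
        X_test = _zscore_columns(dataset.values[test_p].mean(axis=0)[:, cols])
        ranked_fold = np.empty((n_words, n_words), dtype=int)
        acc = np.empty(n_words)
        for w in range(n_words):
            ranked, _ = gnb_rank(model, X_test[w])
            ranked_fold[w] = ranked
            acc[w] = rank_accuracy(_rank_of(ranked, w), n_words)
        out[test_p] = DecodingResult(
            fold_ranked=[ranked_fold],
            fold_accuracy=acc[None, :],
            feature_sets=[feats],
        )
    return out


def permutation_threshold(
    cv_callable: Callable[[np.ndarray], float],
    n_words: int,
    n_permutations: int,
    alpha: float = 0.001,
    seed: int = 0,
    return_distribution: bool = False,
):
    """Empirical (1 - alpha) quantile of mean accuracy under label permutation.

    ``cv_callable`` re-runs the full cross-validation with the given
    permutation applied to training labels and returns the mean accuracy.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    rng = np.random.default_rng(seed)
    accs = np.array(
        [cv_callable(rng.permutation(n_words)) for _ in range(n_permutations)]
    )
    threshold = float(np.quantile(accs, 1 - alpha, method="higher"))
    if return_distribution:
        return threshold, accs
    return threshold
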