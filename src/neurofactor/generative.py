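"""Theory-based generative prediction of activation for unseen words.

At each fold two words are held out; the factor pipeline is re-run on the
remaining words, classifier voxels are re-selected, and a per-voxel linear
regression maps semantic predictors to activation. For the held-out pair the
predictor values come from behavioural ratings of the words on the semantic
dimensions (plus the word's letter count), so the model predicts activation
for words it has never seen, and the two predicted images are matched to the
two observed images by cosine similarity. Accuracy is the fraction of the
C(60, 2) = 1,770 pairs (or a seeded subsample) matched correctly, with an
exact binomial chance threshold.

Scale alignment between training predictors (factor scores) and test
predictors (ratings) is handled by z-scoring each against the training
words; a "ratings" mode that uses ratings on both sides is also provided,
and is the exact limit when activation is a linear function of the rated
dimensions.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment
from scipy.stats import binom

from .dataset import ActivationDataset
from .decoding import FactorContext, FeaturePolicy, build_factor_context, select_features
from .synthetic import WORD_LENGTH_FACTOR
from .words import WordSet

__all__ = [
    "GenerativeModel",
    "MatchResult",
    "build_design",
    "fit_generative",
    "predict_and_match",
    "leave_two_words_out",
    "cross_participant_generative",
    "chance_match_threshold",
]


@dataclass
class GenerativeModel:
    """Per-voxel OLS coefficients over the semantic predictors + intercept."""

    coefficients: np.ndarray  # (n_predictors + 1, n_voxels)
    predictor_names: tuple[str, ...]
    voxel_ids: np.ndarray


@dataclass
class MatchResult:
    """Per-fold pair-matching outcomes and their mean accuracy."""

    pairs: list[tuple[int, int]]
    correct: np.ndarray
    details: pd.DataFrame | None = field(default=None, repr=False)

    @property
    def mean_accuracy(self) -> float:
        return float(np.mean(self.correct))


# ----------------------------------------------------------------------
# design matrices


def _zscore_train(col: np.ndarray) -> tuple[np.ndarray, float, float]:
    m, s = float(col.mean()), float(col.std(ddof=1))
    if s == 0:
        raise ValueError("constant predictor column")
    return (col - m) / s, m, s


def build_design(
    train_predictors: np.ndarray,
    test_predictors: np.ndarray | None = None,
    names: Sequence[str] = (),
) -> tuple[np.ndarray, np.ndarray | None]:
    """Standardize predictor columns against the training words and append an
    intercept; test rows are standardized with the training statistics of
    their own source columns."""
    train = np.asarray(train_predictors, dtype=float)
    if train.ndim != 2:
        raise ValueError("predictors must be (words, predictors)")
    if not np.isfinite(train).all():
        raise ValueError("missing or non-finite predictor value")
    cols, stats = [], []
    for j in range(train.shape[1]):
        z, m, s = _zscore_train(train[:, j])
        cols.append(z)
        stats.append((m, s))
    X = np.column_stack(cols + [np.ones(train.shape[0])])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("design matrix is rank deficient")
    X_test = None
    if test_predictors is not None:
        test = np.atleast_2d(np.asarray(test_predictors, dtype=float))
        if not np.isfinite(test).all():
            raise ValueError("missing or non-finite predictor value")
        zt = [
            (test[:, j] - m) / s for j, (m, s) in enumerate(stats)
        ]
        X_test = np.column_stack(zt + [np.ones(test.shape[0])])
    return X, X_test


def fit_generative(
    design: np.ndarray,
    activations: np.ndarray,
    predictor_names: Sequence[str] = (),
    voxel_ids: np.ndarray | None = None,
) -> GenerativeModel:
    """Independent ordinary least squares per voxel."""
    X = np.asarray(design, dtype=float)
    Y = np.asarray(activations, dtype=float)
    if X.shape[0] != Y.shape[0]:
        raise ValueError("design and activations disagree on word count")
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise np.linalg.LinAlgError("rank-deficient design matrix")
    B, *_ = np.linalg.lstsq(X, Y, rcond=None)
    return GenerativeModel(
        coefficients=B,
        predictor_names=tuple(predictor_names),
        voxel_ids=voxel_ids if voxel_ids is not None else np.arange(Y.shape[1]),
    )


def _cosine(a: np.ndarray, b: np.ndarray) -> float:
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        raise ValueError("zero-norm image in cosine similarity")
    return float(a @ b / (na * nb))


def predict_and_match(
    model: GenerativeModel,
    test_design: np.ndarray,
    observed: np.ndarray,
) -> tuple[bool, dict]:
    """Match two predicted images to two observed images by total cosine.

    The straight pairing wins iff cos(p1,o1)+cos(p2,o2) strictly exceeds the
    swapped total; exact ties count as incorrect (conservative).
    """
    pred = np.asarray(test_design, dtype=float) @ model.coefficients
    obs = np.asarray(observed, dtype=float)
    if pred.shape != obs.shape or pred.shape[0] != 2:
        raise ValueError("need exactly two predicted and two observed images")
    straight = _cosine(pred[0], obs[0]) + _cosine(pred[1], obs[1])
    swapped = _cosine(pred[0], obs[1]) + _cosine(pred[1], obs[0])
    return straight > swapped, {"straight": straight, "swapped": swapped}


# ----------------------------------------------------------------------
# fold machinery


def _ratings_matrix(
    ratings: pd.DataFrame, words: Sequence[str]
) -> tuple[np.ndarray, tuple[str, ...]]:
    """Ratings (+ word length) rows aligned to the given word order."""
    table = ratings.set_index("word")
    missing = [w for w in words if w not in table.index]
    if missing:
        raise ValueError(f"no ratings for {missing[:5]}")
    cols = [c for c in ratings.columns if c != "word"]
    mat = table.loc[list(words), cols].to_numpy(dtype=float)
    return mat, tuple(cols)


def _match_factors_to_predictors(
    context: FactorContext, targets: np.ndarray
) -> tuple[list[int], np.ndarray]:
    """Assign each predictor column its best-matching factor by |r| (Hungarian),
    with the sign that makes the correlation positive."""
    factor_ids = sorted(context.factor_profiles)
    F = np.vstack([context.factor_profiles[k] for k in factor_ids])
    n_t = targets.shape[1]
    corr = np.corrcoef(np.vstack([targets.T, F]))[:n_t, n_t:]
    rows, cols = linear_sum_assignment(-np.abs(corr))
    matched = [0] * n_t
    signs = np.ones(n_t)
    for i, j in zip(rows, cols):
        matched[i] = factor_ids[j]
        signs[i] = 1.0 if corr[i, j] >= 0 else -1.0
    return matched, signs


def _participant_images(
    dataset: ActivationDataset, participant: int, voxel_ids: np.ndarray
) -> np.ndarray:
    """Mean-over-presentations images (words x selected voxels)."""
    return dataset.values[participant].mean(axis=0)[:, voxel_ids]


def _normalize_with_train(
    Y: np.ndarray, train_rows: np.ndarray
) -> np.ndarray:
    """Z-score voxel columns using statistics of the training rows only, so
    held-out rows never leak into the normalization."""
    m = Y[train_rows].mean(axis=0)
    s = Y[train_rows].std(axis=0, ddof=1)
    s = np.where(s > 0, s, 1.0)
    return (Y - m) / s


def _enumerate_pairs(
    n_words: int, fold_sample: int | None, seed: int
) -> list[tuple[int, int]]:
    pairs = list(itertools.combinations(range(n_words), 2))
    if fold_sample is None or fold_sample >= len(pairs):
        return pairs
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(pairs), size=fold_sample, replace=False)
    return [pairs[i] for i in sorted(idx)]


def _fold_prediction(
    dataset: ActivationDataset,
    ratings_mat: np.ndarray,
    rating_names: tuple[str, ...],
    pair: tuple[int, int],
    fa_participants: Sequence[int],
    train_participants: Sequence[int],
    test_participant: int,
    predictors: Literal["ratings", "scores+ratings"],
    per_volume: int,
    n_factors: int,
    two_level_kwargs: dict,
) -> tuple[bool, dict]:
    n_words = dataset.n_words
    train_ids = np.array([w for w in range(n_words) if w not in pair])
    test_ids = np.array(pair)
    sub = dataset.subset_words(train_ids)

    context = build_factor_context(
        sub, fa_participants, n_factors=n_factors, **two_level_kwargs
    )
    rate_train = ratings_mat[train_ids]
    rate_test = ratings_mat[test_ids]

    if predictors == "ratings":
        X_train, X_test = build_design(rate_train, rate_test, rating_names)
    else:
        matched, signs = _match_factors_to_predictors(context, rate_train)
        scores = np.column_stack(
            [
                signs[i] * context.factor_profiles[matched[i]]
                for i in range(len(matched))
            ]
        )
        X_train, _ = build_design(scores, None, rating_names)
        _, X_test = build_design(rate_train, rate_test, rating_names)

    stab_scope = (
        train_participants if len(train_participants) > 1 else train_participants[0]
    )
    if context.volumes:
        policy = FeaturePolicy(mode="factor", per_volume=per_volume)
        feats = select_features(sub, stab_scope, None, policy, context)
    else:
        # no localizable factor cluster (e.g. signal-free data): fall back to
        # purely stability-based selection of the same feature count
        policy = FeaturePolicy(mode="stability", n_features=per_volume * 16)
        feats = select_features(sub, stab_scope, None, policy, None)

    Y_rows = []
    for p in train_participants:
        img = _participant_images(dataset, p, feats.voxel_ids)
        Y_rows.append(_normalize_with_train(img, train_ids)[train_ids])
    Y_train = np.vstack(Y_rows)
    X_full = np.vstack([X_train] * len(train_participants))
    model = fit_generative(X_full, Y_train, rating_names, feats.voxel_ids)

    obs_all = _participant_images(dataset, test_participant, feats.voxel_ids)
    obs = _normalize_with_train(obs_all, train_ids)[test_ids]
    return predict_and_match(model, X_test, obs)


def leave_two_words_out(
    dataset: ActivationDataset,
    participant: int,
    ratings: pd.DataFrame,
    fa_participants: Sequence[int] | None = None,
    predictors: Literal["ratings", "scores+ratings"] = "scores+ratings",
    fold_sample: int | None = None,
    per_volume: int = 5,
    n_factors: int = 4,
    seed: int = 0,
    **two_level_kwargs,
) -> MatchResult:
    """Leave-two-words-out generative matching for one participant.

    All C(n_words, 2) pairs are enumerated, or a seeded subsample of
    ``fold_sample`` pairs. The factor pipeline and voxel selection are redone
    per fold on the remaining words (by default using the participant's own
    data; pass ``fa_participants`` to use other participants' analyses).
    """
    ratings_mat, names = _ratings_matrix(ratings, dataset.words)
    if fa_participants is None:
        fa_participants = [participant]
    pairs = _enumerate_pairs(dataset.n_words, fold_sample, seed)
    correct = np.zeros(len(pairs), dtype=bool)
    rows = []
    for i, pair in enumerate(pairs):
        ok, info = _fold_prediction(
            dataset,
            ratings_mat,
            names,
            pair,
            fa_participants=fa_participants,
            train_participants=[participant],
            test_participant=participant,
            predictors=predictors,
            per_volume=per_volume,
            n_factors=n_factors,
            two_level_kwargs=two_level_kwargs,
        )
        correct[i] = ok
        rows.append(
            {
                "word_a": dataset.words[pair[0]],
                "word_b": dataset.words[pair[1]],
                "correct": ok,
                **info,
            }
        )
    return MatchResult(pairs=pairs, correct=correct, details=pd.DataFrame(rows))


def cross_participant_generative(
    dataset: ActivationDataset,
    ratings: pd.DataFrame,
    participants: Sequence[int] | None = None,
    predictors: Literal["ratings", "scores+ratings"] = "scores+ratings",
    fold_sample: int | None = None,
    per_volume: int = 5,
    n_factors: int = 4,
    seed: int = 0,
    **two_level_kwargs,
) -> dict[int, MatchResult]:
    """Generative prediction for unseen words of an unseen participant.

    For each left-out participant the regression is trained on the other
    participants' mean images for the training words; the left-out
    participant's data are used only as the observed images to be matched.
    """
    if participants is None:
        participants = range(dataset.n_participants)
    participants = [int(p) for p in participants]
    if len(participants) < 2:
        raise ValueError("need at least two participants")
    ratings_mat, names = _ratings_matrix(ratings, dataset.words)
    out: dict[int, MatchResult] = {}
    for test_p in participants:
        train_parts = [p for p in participants if p != test_p]
        pairs = _enumerate_pairs(dataset.n_words, fold_sample, seed + test_p)
        correct = np.zeros(len(pairs), dtype=bool)
        for i, pair in enumerate(pairs):
            ok, _ = _fold_prediction(
                dataset,
                ratings_mat,
                names,
                pair,
                fa_participants=train_parts,
                train_participants=train_parts,
                test_participant=test_p,
                predictors=predictors,
                per_volume=per_volume,
                n_factors=n_factors,
                two_level_kwargs=two_level_kwargs,
            )
            correct[i] = ok
        out[test_p] = MatchResult(pairs=pairs, correct=correct)
    return out


def chance_match_threshold(n_trials: int, alpha: float = 0.001) -> float:
    """Smallest proportion k/n whose exact binomial tail P(X >= k | n, 1/2)
    is at or below alpha."""
    if n_trials < 1:
        raise ValueError("need at least one trial")
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    ks = np.arange(n_trials + 1)
    tail = binom.sf(ks - 1, n_trials, 0.5)
    ok = np.flatnonzero(tail <= alpha)
    if ok.size == 0:
        return float("nan")
    return float(ks[ok[0]] / n_trials)
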