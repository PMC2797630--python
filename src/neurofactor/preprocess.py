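"""Normalisation, per-voxel stability scoring and stable-voxel selection.

A voxel's *stability* is the average pairwise Pearson correlation between
its word activation profiles across repeated presentations of the word set;
it is the reliability screen through which every downstream analysis sees
the data. All SDs use the sample convention (denominator n-1), and ranking
ties are broken by ascending voxel id, so results are fully deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import numpy as np

from .dataset import ActivationDataset

__all__ = [
    "VoxelProfileSet",
    "normalize_within_image",
    "mean_word_profiles",
    "normalize_across_words",
    "voxel_stability",
    "select_stable_voxels",
]


@dataclass
class VoxelProfileSet:
    """Voxels x words profile matrix, with the presentations it averages."""

    profiles: np.ndarray
    voxel_ids: np.ndarray
    presentation_ids: tuple[int, ...]
    normalized: bool = False


def normalize_within_image(image: np.ndarray) -> np.ndarray:
    """Z-score one image across voxels (sample SD).

    Raises on constant images, where the z-score is undefined.
    """
    image = np.asarray(image, dtype=float)
    if image.size < 2:
        raise ValueError("need at least two voxels to normalize an image")
    sd = image.std(ddof=1)
    if sd == 0:
        raise ValueError("constant image: z-score undefined")
    return (image - image.mean()) / sd


def _check_presentations(dataset: ActivationDataset, presentations) -> np.ndarray:
    if presentations is None:
        presentations = range(dataset.n_presentations)
    pres = np.asarray(sorted(presentations), dtype=int)
    if pres.size == 0:
        raise ValueError("presentation subset is empty")
    if pres.min() < 0 or pres.max() >= dataset.n_presentations:
        raise KeyError(f"unknown presentation ids in {pres.tolist()}")
    return pres


def mean_word_profiles(
    dataset: ActivationDataset,
    participant: int,
    presentations: Iterable[int] | None = None,
) -> VoxelProfileSet:
    """Voxels x words mean activation over a presentation subset (unnormalized)."""
    if not 0 <= participant < dataset.n_participants:
        raise KeyError(f"unknown participant {participant}")
    pres = _check_presentations(dataset, presentations)
    prof = dataset.values[participant, pres].mean(axis=0).T  # voxels x words
    return VoxelProfileSet(
        profiles=prof,
        voxel_ids=np.arange(dataset.n_voxels),
        presentation_ids=tuple(int(r) for r in pres),
    )


def normalize_across_words(profiles: VoxelProfileSet) -> VoxelProfileSet:
    """Z-score every voxel's profile across words (mean 0, SD 1 per row)."""
    p = np.asarray(profiles.profiles, dtype=float)
    sd = p.std(axis=1, ddof=1)
    bad = np.flatnonzero(sd == 0)
    if bad.size:
        raise ValueError(
            f"constant word profile for voxel id(s) "
            f"{profiles.voxel_ids[bad[:5]].tolist()}: cannot normalize"
        )
    z = (p - p.mean(axis=1, keepdims=True)) / sd[:, None]
    return VoxelProfileSet(
        profiles=z,
        voxel_ids=profiles.voxel_ids,
        presentation_ids=profiles.presentation_ids,
        normalized=True,
    )


def _profile_stack(
    dataset: ActivationDataset,
    participants: Sequence[int],
    presentations: np.ndarray,
) -> np.ndarray:
    """Stack of word profiles, shape (n_profiles, n_words, n_voxels).

    Within one participant each presentation is a profile; across several
    participants each participant's mean over the given presentations acts
    as one profile (ten participants ~ ten presentations).
    """
    if len(participants) == 1:
        return dataset.values[participants[0], presentations]
    return np.stack(
        [dataset.values[p, presentations].mean(axis=0) for p in participants]
    )


def voxel_stability(
    dataset: ActivationDataset,
    participants: int | Sequence[int],
    presentations: Iterable[int] | None = None,
    on_constant: Literal["error", "zero"] = "error",
) -> np.ndarray:
    """Mean pairwise correlation of each voxel's word profiles.

    For a single participant the profiles are its individual presentations;
    for several participants (cross-participant training scope) each
    participant contributes its mean profile over the given presentations.
    ``on_constant`` controls degenerate profiles with zero variance across
    words: ``"error"`` raises naming the voxel and pair, ``"zero"`` scores
    any pair involving one as 0 (maximally unstable).
    """
    if np.isscalar(participants):
        participants = [int(participants)]  # type: ignore[list-item]
    participants = list(participants)  # type: ignore[arg-type]
    pres = _check_presentations(dataset, presentations)
    stack = _profile_stack(dataset, participants, pres)  # profiles x words x voxels
    n_prof, n_words, _ = stack.shape
    if n_prof < 2:
        raise ValueError("need at least two profiles to compute stability")
    centred = stack - stack.mean(axis=1, keepdims=True)
    sd = stack.std(axis=1, ddof=1)
    degenerate = sd == 0
    if degenerate.any():
        if on_constant == "error":
            prof_i, vox = np.argwhere(degenerate)[0]
            raise ValueError(
                f"voxel {vox} has a constant profile in presentation/profile "
                f"{prof_i}: pairwise correlation undefined"
            )
        sd = np.where(degenerate, 1.0, sd)
    z = centred / sd[:, None, :]
    # corr(a, b) per voxel = z_a . z_b / (n_words - 1)
    corr_sum = np.zeros(stack.shape[2])
    n_pairs = 0
    for a in range(n_prof):
        for b in range(a + 1, n_prof):
            pair = (z[a] * z[b]).sum(axis=0) / (n_words - 1)
            if degenerate.any():
                pair = np.where(degenerate[a] | degenerate[b], 0.0, pair)
            corr_sum += pair
            n_pairs += 1
    return corr_sum / n_pairs


def select_stable_voxels(
    scores: np.ndarray,
    n: int,
    dataset: ActivationDataset | None = None,
    scope: Literal["all", "per-region"] = "all",
) -> np.ndarray:
    """Ids of the ``n`` most stable voxels (ties to the lower voxel id).

    With ``scope="per-region"`` the top ``n`` are taken within every lobe
    separately and concatenated in canonical region order.
    """
    scores = np.asarray(scores, dtype=float)
    if scope == "per-region":
        if dataset is None:
            raise ValueError("per-region selection needs the dataset for labels")
        out = []
        from .dataset import REGIONS

        for region in REGIONS:
            ids = dataset.region_voxels(region)
            out.append(ids[_top_n(scores[ids], n)])
        return np.concatenate(out)
    return _top_n(scores, n)


def _top_n(scores: np.ndarray, n: int) -> np.ndarray:
    if n > scores.size:
        raise ValueError(f"requested {n} voxels but only {scores.size} available")
    # stable sort on -score keeps ascending-index order within ties
    order = np.argsort(-scores, kind="stable")
    return order[:n]
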