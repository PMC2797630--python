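"""Synthetic multi-participant activation datasets with planted factor structure.

The generator emulates the statistical situation the analysis pipeline
assumes: a small number of latent semantic dimensions (plus a word-length
dimension tracking the printed form of the word), each expressed in a handful
of compact voxel clusters distributed over the five lobes, shared across
participants up to a scalar gain, and observed through independent Gaussian
noise at the per-presentation level.

Activation of voxel i for word w, presentation r, participant p:

    a[p, r, w, i] = gain_p * sum_k loadings[i, k] * profiles[k, w] + eps

with ``eps ~ N(0, noise_sd^2)`` and ``gain_p ~ N(1, participant_gain_sd^2)``.
Factor profiles are z-scored over words, and in-cluster loadings have
magnitude ~1, so ``noise_sd`` is directly interpretable as a fraction of the
per-voxel signal SD.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dataset import REGIONS, ActivationDataset
from .words import WordSet, builtin_wordset

__all__ = [
    "SyntheticConfig",
    "GroundTruth",
    "generate_dataset",
    "generate_ratings",
    "semantic_factor_names",
]

# category weights used to compose the three canonical semantic profiles;
# chosen so the top-scoring words mimic the qualitative composition a
# shelter / manipulation / eating decomposition of this word set should show
_SEMANTIC_THEMES: dict[str, dict[str, float]] = {
    "shelter": {"buildings": 1.0, "building parts": 0.8, "vehicles": 0.7},
    "manipulation": {"tools": 1.0, "kitchen utensils": 0.6, "man-made objects": 0.4},
    "eating": {"vegetables": 1.0, "kitchen utensils": 0.7, "animals": 0.3},
}

WORD_LENGTH_FACTOR = "word_length"


def semantic_factor_names(n_semantic: int) -> tuple[str, ...]:
    base = tuple(_SEMANTIC_THEMES)
    if n_semantic <= len(base):
        return base[:n_semantic]
    return base + tuple(f"semantic_{i}" for i in range(len(base), n_semantic))


@dataclass(frozen=True)
class SyntheticConfig:
    """Generation parameters. Defaults are the canonical study conditions:

    six presentations per word, a 10 x 10 x 15 grid of 3.125 x 3.125 x 6 mm
    voxels split into five equal lobe slabs, four latent factors (three
    semantic plus word length) with four planted clusters each (16 clusters
    total), per-presentation noise at 0.3 of the in-cluster signal SD and a
    10% between-participant gain SD.
    """

    n_participants: int = 4
    n_presentations: int = 6
    grid_dims: tuple[int, int, int] = (10, 10, 15)
    voxel_size_mm: tuple[float, float, float] = (3.125, 3.125, 6.0)
    grid_origin_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)
    n_factors: int = 4
    clusters_per_factor: int = 4
    cluster_radius: float = 1.5
    loading_range: tuple[float, float] = (0.8, 1.2)
    noise_sd: float = 0.3
    participant_gain_sd: float = 0.1
    signal_scale: float = 1.0
    shared_code: bool = True
    profile_jitter_sd: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_participants < 1:
            raise ValueError("need at least one participant")
        if self.n_presentations < 2:
            raise ValueError("need at least two presentations")
        if not (math.isfinite(self.noise_sd) and self.noise_sd >= 0):
            raise ValueError("noise_sd must be finite and non-negative")
        if self.participant_gain_sd < 0:
            raise ValueError("participant_gain_sd must be non-negative")
        if self.n_factors < 1:
            raise ValueError("need at least one factor")
        nz = self.grid_dims[2]
        if nz < len(REGIONS):
            raise ValueError("grid too small: need at least one z-slice per region")


@dataclass
class GroundTruth:
    """Planted structure behind a synthetic dataset.

    ``factor_profiles`` (factors x words) are z-scored over words;
    ``loadings`` (voxels x factors) are nonzero only inside planted clusters;
    ``clusters`` is a table with one row per planted cluster (factor, region,
    centre indices, radius, member count).
    """

    factor_names: tuple[str, ...]
    factor_profiles: np.ndarray
    loadings: np.ndarray
    clusters: pd.DataFrame
    cluster_members: list[np.ndarray] = field(default_factory=list)

    def members_of_factor(self, k: int) -> np.ndarray:
        """All voxel ids with a nonzero loading on factor ``k``."""
        return np.flatnonzero(self.loadings[:, k] != 0)


# ----------------------------------------------------------------------
# grid / cluster geometry


def _region_slabs(nz: int) -> list[tuple[int, int]]:
    """Split nz z-slices into five contiguous slabs (start, stop)."""
    edges = np.linspace(0, nz, len(REGIONS) + 1).round().astype(int)
    return [(int(a), int(b)) for a, b in zip(edges[:-1], edges[1:])]


def _region_map(grid_dims: tuple[int, int, int]) -> np.ndarray:
    nx, ny, nz = grid_dims
    labels = np.empty(nx * ny * nz, dtype=object)
    coords = _grid_coords(grid_dims)
    slabs = _region_slabs(nz)
    for region, (a, b) in zip(REGIONS, slabs):
        labels[(coords[:, 2] >= a) & (coords[:, 2] < b)] = region
    return labels


def _grid_coords(grid_dims: tuple[int, int, int]) -> np.ndarray:
    nx, ny, nz = grid_dims
    return (
        np.stack(
            np.meshgrid(np.arange(nx), np.arange(ny), np.arange(nz), indexing="ij"),
            axis=-1,
        )
        .reshape(-1, 3)
        .astype(int)
    )


def _cluster_slots(config: SyntheticConfig) -> dict[str, list[np.ndarray]]:
    """Non-overlapping candidate sphere centres per region.

    Centres sit on an x-y lattice with spacing wide enough that radius-r
    spheres cannot share voxels, at the central z-slice of each lobe slab.
    """
    nx, ny, nz = config.grid_dims
    r = int(math.ceil(config.cluster_radius))
    margin = r
    step = 2 * r + 1
    xs = list(range(margin, nx - margin, step))
    ys = list(range(margin, ny - margin, step))
    slabs = _region_slabs(nz)
    slots: dict[str, list[np.ndarray]] = {}
    for region, (a, b) in zip(REGIONS, slabs):
        if b - a < 2 * r + 1:
            zc = (a + b) // 2  # sphere will be clipped by the slab filter below
        else:
            zc = a + r + (b - a - 2 * r - 1) // 2
        slots[region] = [np.array([x, y, zc]) for x in xs for y in ys]
    return slots


def plant_clusters(config: SyntheticConfig) -> tuple[np.ndarray, pd.DataFrame, list[np.ndarray]]:
    """Place ``n_factors x clusters_per_factor`` spherical clusters.

    Cluster c of factor f is confined to region ``(f + c) mod 5`` so each
    factor spans several lobes and each lobe hosts several factors. The x-y
    slot within the region is tied to the cluster index so a factor never
    occupies the same column in two adjacent lobe slabs (which would fuse
    its clusters across the slab boundary). Returns the per-voxel factor
    index (-1 outside clusters), the cluster table and per-cluster member
    voxel-id arrays.
    """
    coords = _grid_coords(config.grid_dims)
    slots = _cluster_slots(config)
    occupied: set[tuple[str, int]] = set()
    voxel_factor = np.full(len(coords), -1, dtype=int)
    rows = []
    members: list[np.ndarray] = []
    slabs = dict(zip(REGIONS, _region_slabs(config.grid_dims[2])))
    for f in range(config.n_factors):
        for c in range(config.clusters_per_factor):
            region = REGIONS[(f + c) % len(REGIONS)]
            if c >= len(slots[region]) or (region, c) in occupied:
                raise ValueError(
                    f"grid {config.grid_dims} too small to host "
                    f"{config.clusters_per_factor} clusters per factor: "
                    f"region {region!r} has only {len(slots[region])} free slots"
                )
            centre = slots[region][c]
            occupied.add((region, c))
            d2 = ((coords - centre) ** 2).sum(axis=1)
            inside = d2 <= config.cluster_radius**2 + 1e-12
            a, b = slabs[region]
            inside &= (coords[:, 2] >= a) & (coords[:, 2] < b)
            ids = np.flatnonzero(inside)
            if len(ids) < 5:
                raise ValueError(
                    f"cluster radius {config.cluster_radius} yields fewer than "
                    f"5 voxels in region {region!r}"
                )
            if (voxel_factor[ids] != -1).any():
                raise ValueError("planted clusters overlap; enlarge the grid")
            voxel_factor[ids] = f
            members.append(ids)
            rows.append(
                {
                    "factor": f,
                    "region": region,
                    "ci": int(centre[0]),
                    "cj": int(centre[1]),
                    "ck": int(centre[2]),
                    "radius": config.cluster_radius,
                    "n_voxels": len(ids),
                }
            )
    return voxel_factor, pd.DataFrame(rows), members


# ----------------------------------------------------------------------
# factor profiles


def _zscore(x: np.ndarray) -> np.ndarray:
    sd = x.std(ddof=1)
    if sd == 0:
        raise ValueError("cannot z-score a constant vector")
    return (x - x.mean()) / sd


def _keyed_rng(seed: int, name: str, tag: int) -> np.random.Generator:
    """RNG keyed by (seed, string, tag) so draws follow the string, not the
    position: permuting word order permutes the planted profiles identically."""
    return np.random.default_rng(
        [seed & 0x7FFFFFFF, zlib.crc32(name.encode()), tag]
    )


def make_factor_profiles(
    words: WordSet, n_factors: int, jitter_sd: float, seed: int
) -> tuple[np.ndarray, tuple[str, ...]]:
    """Semantic profiles from smooth category mixtures plus a word-length profile.

    The final factor is always the z-scored letter count; the preceding ones
    are category-weight mixtures with per-word jitter, z-scored over words.
    """
    n_semantic = n_factors - 1
    names = semantic_factor_names(max(n_semantic, 0))
    profiles = []
    cats = np.asarray(words.categories)
    for k, name in enumerate(names):
        theme = _SEMANTIC_THEMES.get(name)
        if theme is None:
            weights = {
                c: float(_keyed_rng(seed, c, 1000 + k).uniform(0, 1))
                for c in words.category_names
            }
        else:
            weights = theme
        base = np.array([weights.get(c, 0.0) for c in cats], dtype=float)
        jitter = np.array(
            [float(_keyed_rng(seed, w, k).normal(0.0, 1.0)) for w in words.words]
        )
        profiles.append(_zscore(base + jitter_sd * jitter))
    profiles.append(_zscore(np.asarray(words.lengths, dtype=float)))
    return np.vstack(profiles), names + (WORD_LENGTH_FACTOR,)


# ----------------------------------------------------------------------
# dataset generation


def generate_dataset(
    config: SyntheticConfig, words: WordSet | None = None
) -> tuple[ActivationDataset, GroundTruth]:
    """Generate a multi-participant dataset and its planted ground truth.

    Identical ``config`` (including seed) gives bitwise-identical output.
    With ``shared_code=False`` each participant's loading matrix is passed
    through its own seeded voxel permutation: the latent code stays intact
    within a participant but its spatial layout is idiosyncratic, which
    breaks cross-participant transfer by construction.
    """
    if words is None:
        words = builtin_wordset()
    rng = np.random.default_rng(config.seed)
    voxel_factor, clusters, members = plant_clusters(config)
    n_voxels = len(voxel_factor)
    profiles, names = make_factor_profiles(
        words, config.n_factors, config.profile_jitter_sd, config.seed
    )

    loadings = np.zeros((n_voxels, config.n_factors))
    lo, hi = config.loading_range
    for k in range(config.n_factors):
        ids = np.flatnonzero(voxel_factor == k)
        loadings[ids, k] = rng.uniform(lo, hi, len(ids)) * config.signal_scale

    gains = 1.0 + rng.normal(0.0, 1.0, config.n_participants) * config.participant_gain_sd
    n_w = len(words)
    values = np.empty(
        (config.n_participants, config.n_presentations, n_w, n_voxels)
    )
    for p in range(config.n_participants):
        load_p = loadings
        if not config.shared_code:
            perm = rng.permutation(n_voxels)
            load_p = loadings[perm]
        signal = gains[p] * (profiles.T @ load_p.T)  # words x voxels
        noise = rng.normal(
            0.0, 1.0, (config.n_presentations, n_w, n_voxels)
        ) * config.noise_sd
        values[p] = signal[None, :, :] + noise

    dataset = ActivationDataset(
        values=values,
        voxel_coords=_grid_coords(config.grid_dims),
        voxel_size_mm=config.voxel_size_mm,
        grid_origin_mm=config.grid_origin_mm,
        region_labels=_region_map(config.grid_dims),
        words=tuple(words.words),
        grid_dims=config.grid_dims,
    )
    truth = GroundTruth(
        factor_names=names,
        factor_profiles=profiles,
        loadings=loadings,
        clusters=clusters,
        cluster_members=members,
    )
    return dataset, truth


# ----------------------------------------------------------------------
# ratings


def generate_ratings(
    truth: GroundTruth,
    words: WordSet,
    rating_noise_sd: float = 0.5,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-word 1-7 ratings for each semantic factor, plus word length.

    Each semantic factor profile is affinely rescaled into [1, 7]; Gaussian
    noise with the given SD (on the 1-7 scale) is added and the result is
    clipped back into [1, 7]. At ``rating_noise_sd=0`` every rating column
    is a perfect affine image of its factor profile.
    """
    semantic = [n for n in truth.factor_names if n != WORD_LENGTH_FACTOR]
    if not semantic:
        raise ValueError("ground truth has no semantic factor")
    rng = np.random.default_rng(seed)
    data: dict[str, object] = {"word": list(words.words)}
    for name in semantic:
        prof = truth.factor_profiles[truth.factor_names.index(name)]
        lo, hi = prof.min(), prof.max()
        scaled = 1.0 + 6.0 * (prof - lo) / (hi - lo)
        noisy = scaled + rng.normal(0.0, rating_noise_sd, len(prof))
        data[name] = np.clip(noisy, 1.0, 7.0)
    data["length"] = list(words.lengths)
    return pd.DataFrame(data)
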