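"""Two-level exploratory factor analysis of voxel activation profiles.

Level 1 runs principal axis factoring (PAF) with varimax rotation on the
correlation matrix of the 50 most stable voxels of each lobe of each
participant, modelling each voxel profile v_i as a linear combination of
factor profiles. Level 2 factors the pooled first-level factor profiles to
find dimensions common across lobes and participants (higher-order factor
analysis). Factor profiles (factor scores per word) are recovered from the
loadings by ordinary least squares. Items are assigned to the factor with
the highest absolute loading when it exceeds a 0.4 threshold, and a
second-level factor's commonality is the number of participants whose
voxels map to it.

PAF specifics: initial communalities are squared multiple correlations,
the reduced correlation matrix is re-eigendecomposed with communality
updates until the largest communality change is below ``tol`` (default
1e-3, at most ``max_iter`` iterations); negative eigenvalues of the reduced
matrix are clamped to zero. Varimax uses Kaiser row normalisation. Each
factor's sign is flipped so its largest-magnitude loading is positive, and
rotated factors are ordered by explained sum of squares, so outputs are
deterministic up to those conventions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

from .dataset import REGIONS, ActivationDataset
from .preprocess import (
    mean_word_profiles,
    normalize_across_words,
    select_stable_voxels,
    voxel_stability,
    VoxelProfileSet,
)

__all__ = [
    "FactorModel",
    "TwoLevelFactorModel",
    "PAFConvergenceError",
    "principal_axis_factoring",
    "varimax_rotate",
    "varimax_criterion",
    "solve_factor_profiles",
    "assign_by_max_loading",
    "first_level_analysis",
    "second_level_analysis",
    "run_two_level",
    "single_level_analysis",
    "align_factors",
]


class PAFConvergenceError(RuntimeError):
    """PAF failed to converge; carries the communality-change trace."""

    def __init__(self, trace: list[float]):
        self.trace = trace
        super().__init__(
            f"principal axis factoring did not converge in {len(trace)} "
            f"iterations (last communality change {trace[-1]:.3g})"
        )


@dataclass
class FactorModel:
    """One factor analysis: loadings, word profiles and eigenvalues.

    ``level`` is 1 (items are voxels) or 2 (items are first-level factors).
    ``item_ids`` records item provenance: voxel ids at level 1, and
    (participant, region, factor) triples at level 2.
    """

    level: int
    loadings: np.ndarray
    profiles: np.ndarray
    eigenvalues: np.ndarray
    item_ids: list = field(default_factory=list)

    @property
    def n_factors(self) -> int:
        return self.loadings.shape[1]

    def communalities(self) -> np.ndarray:
        return (self.loadings**2).sum(axis=1)

    def explained_share(self) -> np.ndarray:
        """Per-factor share of item variation: sum of squared loadings / items."""
        return (self.loadings**2).sum(axis=0) / self.loadings.shape[0]


# ----------------------------------------------------------------------
# extraction and rotation


def _smc(R: np.ndarray) -> np.ndarray:
    """Squared multiple correlations, the standard initial communalities."""
    diag_inv = np.diag(np.linalg.pinv(R))
    with np.errstate(divide="ignore"):
        smc = 1.0 - 1.0 / np.where(diag_inv > 0, diag_inv, np.inf)
    return np.clip(smc, 0.0, 0.995)


def principal_axis_factoring(
    R: np.ndarray,
    k: int,
    tol: float = 1e-3,
    max_iter: int = 1000,
) -> tuple[np.ndarray, np.ndarray]:
    """Iterated PAF on a correlation matrix; returns (loadings, eigenvalues).

    Loadings are unrotated, in non-increasing eigenvalue order.
    """
    R = np.asarray(R, dtype=float)
    n = R.shape[0]
    if R.shape != (n, n) or not np.allclose(R, R.T, atol=1e-8):
        raise ValueError("R must be a symmetric square matrix")
    if not np.allclose(np.diag(R), 1.0, atol=1e-6):
        raise ValueError("R must have a unit diagonal (correlation matrix)")
    if not 1 <= k < n:
        raise ValueError(f"k={k} must be in [1, {n - 1}]")
    h = _smc(R)
    trace: list[float] = []
    for _ in range(max_iter):
        reduced = R.copy()
        np.fill_diagonal(reduced, h)
        eigval, eigvec = np.linalg.eigh(reduced)
        eigval, eigvec = eigval[::-1], eigvec[:, ::-1]
        eigval = np.clip(eigval, 0.0, None)  # clamp non-PSD leakage
        loadings = eigvec[:, :k] * np.sqrt(eigval[:k])
        h_new = np.minimum((loadings**2).sum(axis=1), 1.0)
        delta = float(np.abs(h_new - h).max())
        trace.append(delta)
        h = h_new
        if delta < tol:
            return loadings, eigval[:k]
    raise PAFConvergenceError(trace)


def _drop_null_factors(
    loadings: np.ndarray, eigenvalues: np.ndarray, tol: float = 1e-8
) -> tuple[np.ndarray, np.ndarray]:
    """Discard factors with (numerically) zero eigenvalue.

    With exactly rank-deficient input (e.g. noise-free synthetic data) the
    requested number of factors can exceed the dimensions of common
    variance; the unsupported factors carry all-zero loadings and would make
    the profile solve rank deficient, so only supported factors are kept.
    """
    keep = np.flatnonzero(eigenvalues > tol)
    if keep.size == 0:
        raise ValueError("no factor has positive eigenvalue (no common variance)")
    if keep.size == len(eigenvalues):
        return loadings, eigenvalues
    return loadings[:, keep], eigenvalues[keep]


def varimax_criterion(loadings: np.ndarray, kaiser: bool = True) -> float:
    """Sum over factors of the variance of squared (row-normalised) loadings."""
    L = np.asarray(loadings, dtype=float)
    if kaiser:
        h = np.sqrt((L**2).sum(axis=1))
        h = np.where(h > 0, h, 1.0)
        L = L / h[:, None]
    sq = L**2
    return float((sq.var(axis=0)).sum())


def varimax_rotate(
    loadings: np.ndarray,
    kaiser: bool = True,
    tol: float = 1e-6,
    max_iter: int = 500,
) -> tuple[np.ndarray, np.ndarray]:
    """Varimax rotation; returns (rotated loadings, rotation matrix).

    The rotation matrix includes the final column reordering (by explained
    sum of squares) and sign convention, and stays orthonormal.
    """
    L = np.asarray(loadings, dtype=float)
    n, k = L.shape
    if k < 2:
        rot = np.eye(k)
        return _canonicalize(L, rot)
    h = np.sqrt((L**2).sum(axis=1))
    h = np.where(h > 0, h, 1.0)
    A = (L / h[:, None] if kaiser else L).copy()
    # classical pairwise (planar) sweeps: for every factor pair the optimal
    # rotation angle has a closed form, so each step is a global planar
    # ascent and symmetric configurations cannot stall the iteration
    R = np.eye(k)
    crit_old = varimax_criterion(A, kaiser=False)
    for _ in range(max_iter):
        for p in range(k - 1):
            for q in range(p + 1, k):
                x, y = A[:, p], A[:, q]
                u = x * x - y * y
                v = 2.0 * x * y
                num = 2.0 * (u * v).sum() - 2.0 * u.sum() * v.sum() / n
                den = (u * u - v * v).sum() - (u.sum() ** 2 - v.sum() ** 2) / n
                theta = 0.25 * np.arctan2(num, den)
                c, s = np.cos(theta), np.sin(theta)
                rot = np.array([[c, -s], [s, c]])
                A[:, [p, q]] = A[:, [p, q]] @ rot
                R[:, [p, q]] = R[:, [p, q]] @ rot
        crit = varimax_criterion(A, kaiser=False)
        if crit - crit_old < tol * max(abs(crit), 1e-12):
            break
        crit_old = crit
    rotated = A * (h[:, None] if kaiser else 1.0)
    return _canonicalize(rotated, R)


def _canonicalize(L: np.ndarray, R: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Order factors by explained SS (desc) and make dominant loadings positive."""
    ss = (L**2).sum(axis=0)
    order = np.argsort(-ss, kind="stable")
    L, R = L[:, order], R[:, order]
    signs = np.array([
        1.0 if col[np.argmax(np.abs(col))] >= 0 else -1.0 for col in L.T
    ])
    return L * signs, R * signs


def solve_factor_profiles(loadings: np.ndarray, item_profiles: np.ndarray) -> np.ndarray:
    """Least-squares factor profiles F minimising ||V - C F||^2 columnwise.

    These profiles are the factor scores of each word. Raises on a
    rank-deficient loading matrix rather than silently pseudo-inverting.
    """
    C = np.asarray(loadings, dtype=float)
    V = np.asarray(item_profiles, dtype=float)
    if C.shape[0] != V.shape[0]:
        raise ValueError("loadings and item profiles disagree on item count")
    k = C.shape[1]
    if np.linalg.matrix_rank(C) < k:
        raise np.linalg.LinAlgError("loading matrix is rank deficient")
    F, *_ = np.linalg.lstsq(C, V, rcond=None)
    return F


def assign_by_max_loading(loading_row: np.ndarray, threshold: float = 0.4) -> int | None:
    """Factor index with the highest absolute loading, or None below threshold."""
    row = np.asarray(loading_row, dtype=float)
    j = int(np.argmax(np.abs(row)))
    return j if np.abs(row[j]) >= threshold else None


# ----------------------------------------------------------------------
# pipeline levels


def _normalized_selected_profiles(
    dataset: ActivationDataset,
    participant: int,
    voxel_ids: np.ndarray,
    presentations,
) -> np.ndarray:
    prof = mean_word_profiles(dataset, participant, presentations)
    selected = VoxelProfileSet(
        profiles=prof.profiles[voxel_ids],
        voxel_ids=voxel_ids,
        presentation_ids=prof.presentation_ids,
    )
    return normalize_across_words(selected).profiles


def first_level_analysis(
    dataset: ActivationDataset,
    participant: int,
    region: str,
    n_voxels: int = 50,
    n_factors: int = 5,
    presentations: Sequence[int] | None = None,
    paf_tol: float = 1e-3,
    paf_max_iter: int = 1000,
) -> FactorModel:
    """Factor the n most stable voxels of one lobe of one participant."""
    region_ids = dataset.region_voxels(region)
    if len(region_ids) < n_voxels:
        raise ValueError(
            f"region {region!r} has {len(region_ids)} voxels, need {n_voxels}"
        )
    stability = voxel_stability(
        dataset, participant, presentations, on_constant="zero"
    )
    order = np.argsort(-stability[region_ids], kind="stable")
    voxel_ids = region_ids[order[:n_voxels]]
    z = _normalized_selected_profiles(dataset, participant, voxel_ids, presentations)
    R = np.corrcoef(z)
    loadings, eigenvalues = principal_axis_factoring(
        R, n_factors, tol=paf_tol, max_iter=paf_max_iter
    )
    loadings, eigenvalues = _drop_null_factors(loadings, eigenvalues)
    rotated, _ = varimax_rotate(loadings)
    profiles = solve_factor_profiles(rotated, z)
    return FactorModel(
        level=1,
        loadings=rotated,
        profiles=profiles,
        eigenvalues=eigenvalues,
        item_ids=list(voxel_ids),
    )


def second_level_analysis(
    first_level_profiles: np.ndarray,
    n_factors: int = 10,
    item_ids: list | None = None,
    paf_tol: float = 1e-3,
    paf_max_iter: int = 1000,
) -> FactorModel:
    """Factor the pooled first-level factor profiles (higher-order analysis)."""
    P = np.asarray(first_level_profiles, dtype=float)
    if P.shape[0] < n_factors:
        raise ValueError("need at least n_factors input profiles")
    sd = P.std(axis=1, ddof=1)
    if (sd == 0).any():
        raise ValueError("constant first-level profile cannot be factored")
    z = (P - P.mean(axis=1, keepdims=True)) / sd[:, None]
    R = np.corrcoef(z)
    loadings, eigenvalues = principal_axis_factoring(
        R, n_factors, tol=paf_tol, max_iter=paf_max_iter
    )
    loadings, eigenvalues = _drop_null_factors(loadings, eigenvalues)
    rotated, _ = varimax_rotate(loadings)
    profiles = solve_factor_profiles(rotated, z)
    return FactorModel(
        level=2,
        loadings=rotated,
        profiles=profiles,
        eigenvalues=eigenvalues,
        item_ids=item_ids or list(range(P.shape[0])),
    )


@dataclass
class TwoLevelFactorModel:
    """The chained two-level analysis with voxel-to-factor mapping.

    ``assignments`` has one row per assigned voxel with columns
    (participant, voxel, region, first_factor, second_factor);
    ``commonality`` counts, per second-level factor, the participants whose
    voxels map to it; ``variance_share`` is each second-level factor's share
    of explained variation in the pooled first-level profiles.
    """

    first_level: dict
    second_level: FactorModel
    assignment_threshold: float
    assignments: pd.DataFrame
    commonality: np.ndarray
    variance_share: np.ndarray
    participants: tuple[int, ...]

    def factor_voxels(self, k: int) -> np.ndarray:
        """Unique voxel ids (pooled over participants) assigned to factor k."""
        sel = self.assignments[self.assignments["second_factor"] == k]
        return np.unique(sel["voxel"].to_numpy())


def run_two_level(
    dataset: ActivationDataset,
    participants: Sequence[int] | None = None,
    n_stable_per_lobe: int = 50,
    n_first_factors: int = 5,
    n_second_factors: int = 10,
    assignment_threshold: float = 0.4,
    presentations: Sequence[int] | None = None,
    regions: Sequence[str] = REGIONS,
    paf_tol: float = 1e-3,
    paf_max_iter: int = 1000,
) -> TwoLevelFactorModel:
    """First-level analyses per (participant, lobe), one second-level analysis,
    voxel-to-factor mapping and per-factor participant commonality."""
    if participants is None:
        participants = range(dataset.n_participants)
    participants = tuple(int(p) for p in participants)
    if not participants:
        raise ValueError("need at least one participant")

    first_level: dict = {}
    pooled: list[np.ndarray] = []
    origins: list[tuple[int, str, int]] = []
    for p in participants:
        for region in regions:
            fm = first_level_analysis(
                dataset,
                p,
                region,
                n_voxels=n_stable_per_lobe,
                n_factors=n_first_factors,
                presentations=presentations,
                paf_tol=paf_tol,
                paf_max_iter=paf_max_iter,
            )
            first_level[(p, region)] = fm
            pooled.append(fm.profiles)
            origins.extend((p, region, j) for j in range(fm.n_factors))
    pooled_mat = np.vstack(pooled)
    second = second_level_analysis(
        pooled_mat,
        n_factors=n_second_factors,
        item_ids=origins,
        paf_tol=paf_tol,
        paf_max_iter=paf_max_iter,
    )

    # first-level factor (global item n) -> second-level factor
    upper = [
        assign_by_max_loading(row, assignment_threshold) for row in second.loadings
    ]
    rows = []
    for n_global, (p, region, j) in enumerate(origins):
        K = upper[n_global]
        if K is None:
            continue
        fm = first_level[(p, region)]
        for i, voxel in enumerate(fm.item_ids):
            jj = assign_by_max_loading(fm.loadings[i], assignment_threshold)
            if jj == j:
                rows.append(
                    {
                        "participant": p,
                        "voxel": int(voxel),
                        "region": region,
                        "first_factor": j,
                        "second_factor": K,
                    }
                )
    assignments = pd.DataFrame(
        rows, columns=["participant", "voxel", "region", "first_factor", "second_factor"]
    )
    commonality = np.zeros(second.n_factors, dtype=int)
    for k in range(second.n_factors):
        sel = assignments[assignments["second_factor"] == k]
        commonality[k] = sel["participant"].nunique()
    return TwoLevelFactorModel(
        first_level=first_level,
        second_level=second,
        assignment_threshold=assignment_threshold,
        assignments=assignments,
        commonality=commonality,
        variance_share=second.explained_share(),
        participants=participants,
    )


def single_level_analysis(
    dataset: ActivationDataset,
    participants: Sequence[int] | None = None,
    n_voxels_per_participant: int = 100,
    n_factors: int = 10,
    presentations: Sequence[int] | None = None,
    paf_tol: float = 1e-3,
    paf_max_iter: int = 1000,
) -> FactorModel:
    """One-step variant: pool each participant's most stable cortex voxels
    and factor them jointly, skipping the per-lobe level."""
    if participants is None:
        participants = range(dataset.n_participants)
    participants = tuple(int(p) for p in participants)
    profiles = []
    item_ids: list = []
    for p in participants:
        stability = voxel_stability(dataset, p, presentations, on_constant="zero")
        ids = select_stable_voxels(stability, n_voxels_per_participant)
        profiles.append(
            _normalized_selected_profiles(dataset, p, ids, presentations)
        )
        item_ids.extend((p, int(v)) for v in ids)
    z = np.vstack(profiles)
    R = np.corrcoef(z)
    loadings, eigenvalues = principal_axis_factoring(
        R, n_factors, tol=paf_tol, max_iter=paf_max_iter
    )
    rotated, _ = varimax_rotate(loadings)
    return FactorModel(
        level=1,
        loadings=rotated,
        profiles=solve_factor_profiles(rotated, z),
        eigenvalues=eigenvalues,
        item_ids=item_ids,
    )


def align_factors(
    estimated: np.ndarray, reference: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Match estimated factor profiles to reference profiles.

    Factors are identified only up to order and sign, so matching maximises
    total absolute correlation via the Hungarian algorithm. Returns, for each
    reference factor, the matched estimated index, the sign making the
    correlation positive, and the absolute correlation.
    """
    est = np.asarray(estimated, dtype=float)
    ref = np.asarray(reference, dtype=float)
    n_ref = ref.shape[0]
    corr = np.corrcoef(np.vstack([ref, est]))[:n_ref, n_ref:]
    ref_idx, est_idx = linear_sum_assignment(-np.abs(corr))
    matched = np.empty(n_ref, dtype=int)
    signs = np.empty(n_ref)
    abs_r = np.empty(n_ref)
    for i, j in zip(ref_idx, est_idx):
        matched[i] = j
        signs[i] = 1.0 if corr[i, j] >= 0 else -1.0
        abs_r[i] = abs(corr[i, j])
    return matched, signs, abs_r
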