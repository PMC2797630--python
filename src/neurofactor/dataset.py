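"""In-memory container for per-presentation word-evoked voxel activation.

The activation values are stored as a dense 4-way array indexed
(participant, presentation, word, voxel). Voxels live on a regular 3-D grid
with anisotropic physical voxel size and are partitioned into five bilateral
"lobes" (frontal, parietal, temporal, occipital, fusiform), mirroring the
way preprocessed word-level images are organised for this kind of analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

REGIONS = ("frontal", "parietal", "temporal", "occipital", "fusiform")


@dataclass
class ActivationDataset:
    """Word-evoked activation for several participants and presentations.

    Attributes
    ----------
    values:
        Array of shape ``(n_participants, n_presentations, n_words, n_voxels)``.
    voxel_coords:
        Integer grid index triples, shape ``(n_voxels, 3)``; 0-based.
    voxel_size_mm, grid_origin_mm:
        Physical geometry; mm coordinate = origin + index * voxel_size.
    region_labels:
        Per-voxel lobe label, one of :data:`REGIONS`.
    words:
        Word strings aligned with the word axis.
    """

    values: np.ndarray
    voxel_coords: np.ndarray
    voxel_size_mm: tuple[float, float, float]
    grid_origin_mm: tuple[float, float, float]
    region_labels: np.ndarray
    words: tuple[str, ...]
    grid_dims: tuple[int, int, int] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.voxel_coords = np.asarray(self.voxel_coords, dtype=int)
        self.region_labels = np.asarray(self.region_labels, dtype=object)
        if self.grid_dims is None:
            self.grid_dims = tuple(int(d) for d in self.voxel_coords.max(axis=0) + 1)
        self.validate()

    # -- shape accessors ---------------------------------------------------
    @property
    def n_participants(self) -> int:
        return self.values.shape[0]

    @property
    def n_presentations(self) -> int:
        return self.values.shape[1]

    @property
    def n_words(self) -> int:
        return self.values.shape[2]

    @property
    def n_voxels(self) -> int:
        return self.values.shape[3]

    def word_index(self, word: str) -> int:
        return self.words.index(word)

    def validate(self) -> None:
        if self.values.ndim != 4:
            raise ValueError("values must be 4-way (participant, presentation, word, voxel)")
        if not np.isfinite(self.values).all():
            raise ValueError("activation values contain non-finite entries")
        p, r, w, v = self.values.shape
        if len(self.words) != w:
            raise ValueError(f"word list length {len(self.words)} != word axis {w}")
        if self.voxel_coords.shape != (v, 3):
            raise ValueError("voxel_coords must be (n_voxels, 3)")
        if self.region_labels.shape != (v,):
            raise ValueError("region_labels must be per-voxel")
        unknown = set(map(str, self.region_labels)) - set(REGIONS)
        if unknown:
            raise ValueError(f"unknown region labels: {sorted(unknown)}")

    # -- geometry ----------------------------------------------------------
    def voxel_mm(self, voxel_ids=None) -> np.ndarray:
        """Physical centre coordinates (mm) of the given voxels (default all)."""
        coords = self.voxel_coords if voxel_ids is None else self.voxel_coords[voxel_ids]
        return np.asarray(self.grid_origin_mm) + coords * np.asarray(self.voxel_size_mm)

    def region_voxels(self, region: str) -> np.ndarray:
        """Ids of the voxels carrying the given lobe label."""
        if region not in REGIONS:
            raise KeyError(f"unknown region {region!r}")
        return np.flatnonzero(self.region_labels == region)

    def subset_words(self, word_ids) -> "ActivationDataset":
        """A view-like copy restricted to the given word indices (in order)."""
        word_ids = np.asarray(word_ids, dtype=int)
        return ActivationDataset(
            values=self.values[:, :, word_ids, :],
            voxel_coords=self.voxel_coords,
            voxel_size_mm=self.voxel_size_mm,
            grid_origin_mm=self.grid_origin_mm,
            region_labels=self.region_labels,
            words=tuple(self.words[i] for i in word_ids),
            grid_dims=self.grid_dims,
        )
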