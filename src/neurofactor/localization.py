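"""Mapping factors back to brain locations.

Voxels assigned to a factor tend to aggregate spatially; clusters are
connected components of at least five voxels, each summarised by a sphere at
the cluster centroid with radius equal to the mean radial dispersion of the
member voxels (in mm, so anisotropic voxels are handled by physical
coordinates). For feature selection each sphere is widened into a cuboid
search volume: the sphere's voxel-index bounding box grown by one voxel per
dimension and clipped at the grid edges.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from .dataset import ActivationDataset
from .factors import TwoLevelFactorModel

__all__ = [
    "ClusterLocation",
    "SearchVolume",
    "find_clusters",
    "cluster_sphere",
    "make_search_volume",
    "localize_factors",
    "cluster_report",
]

_STRUCTURES = {
    6: ndimage.generate_binary_structure(3, 1),
    18: ndimage.generate_binary_structure(3, 2),
    26: ndimage.generate_binary_structure(3, 3),
}


@dataclass
class ClusterLocation:
    """A factor-linked voxel cluster summarised as a sphere."""

    factor: int
    voxel_ids: np.ndarray
    centroid_mm: np.ndarray
    radius_mm: float

    @property
    def n_voxels(self) -> int:
        return len(self.voxel_ids)


@dataclass
class SearchVolume:
    """Inclusive cuboid bounds (voxel indices) derived from a cluster sphere."""

    factor: int
    lower: np.ndarray
    upper: np.ndarray
    source: ClusterLocation | None = None

    def contains(self, coords: np.ndarray) -> np.ndarray:
        """Boolean mask of which coordinate rows fall inside the cuboid."""
        coords = np.atleast_2d(coords)
        return ((coords >= self.lower) & (coords <= self.upper)).all(axis=1)

    def voxel_ids(self, dataset: ActivationDataset) -> np.ndarray:
        return np.flatnonzero(self.contains(dataset.voxel_coords))


def find_clusters(
    voxel_ids: Sequence[int],
    dataset: ActivationDataset,
    min_size: int = 5,
    connectivity: int = 26,
) -> list[np.ndarray]:
    """Connected components of the given voxels, discarding small ones.

    ``connectivity`` is 6 (faces), 18 (faces+edges) or 26 (full neighbour
    cube). Components are returned in order of their lowest voxel id.
    """
    if connectivity not in _STRUCTURES:
        raise ValueError("connectivity must be one of 6, 18, 26")
    voxel_ids = np.asarray(voxel_ids, dtype=int)
    if voxel_ids.size == 0:
        return []
    mask = np.zeros(dataset.grid_dims, dtype=bool)
    coords = dataset.voxel_coords[voxel_ids]
    mask[tuple(coords.T)] = True
    labels, n_comp = ndimage.label(mask, structure=_STRUCTURES[connectivity])
    comp_of_voxel = labels[tuple(coords.T)]
    clusters = []
    for comp in range(1, n_comp + 1):
        ids = voxel_ids[comp_of_voxel == comp]
        if len(ids) >= min_size:
            clusters.append(np.sort(ids))
    clusters.sort(key=lambda ids: int(ids[0]))
    return clusters


def cluster_sphere(
    voxel_ids: Sequence[int], dataset: ActivationDataset, factor: int = -1
) -> ClusterLocation:
    """Centroid (mm) and mean radial dispersion (mm) of a voxel cluster."""
    voxel_ids = np.asarray(voxel_ids, dtype=int)
    if voxel_ids.size == 0:
        raise ValueError("cluster must contain at least one voxel")
    centres = dataset.voxel_mm(voxel_ids)
    centroid = centres.mean(axis=0)
    radius = float(np.linalg.norm(centres - centroid, axis=1).mean())
    return ClusterLocation(
        factor=factor,
        voxel_ids=voxel_ids,
        centroid_mm=centroid,
        radius_mm=radius,
    )


def make_search_volume(
    location: ClusterLocation, dataset: ActivationDataset
) -> SearchVolume:
    """Cuboid bounding box of the sphere, grown by one voxel, clipped to grid."""
    size = np.asarray(dataset.voxel_size_mm)
    origin = np.asarray(dataset.grid_origin_mm)
    centre_idx = (location.centroid_mm - origin) / size
    r_idx = location.radius_mm / size
    lower = np.floor(centre_idx - r_idx).astype(int) - 1
    upper = np.ceil(centre_idx + r_idx).astype(int) + 1
    dims = np.asarray(dataset.grid_dims)
    return SearchVolume(
        factor=location.factor,
        lower=np.clip(lower, 0, dims - 1),
        upper=np.clip(upper, 0, dims - 1),
        source=location,
    )


def localize_factors(
    model: TwoLevelFactorModel,
    dataset: ActivationDataset,
    factors: Sequence[int] | None = None,
    min_size: int = 5,
    connectivity: int = 26,
) -> dict[int, list[ClusterLocation]]:
    """Clusters of each second-level factor's assigned voxels.

    Voxel assignments are pooled over participants (a shared coordinate
    frame is assumed). Factors with no surviving cluster map to an empty
    list.
    """
    if factors is None:
        factors = range(model.second_level.n_factors)
    out: dict[int, list[ClusterLocation]] = {}
    for k in factors:
        ids = model.factor_voxels(int(k))
        comps = find_clusters(ids, dataset, min_size=min_size, connectivity=connectivity)
        out[int(k)] = [cluster_sphere(c, dataset, factor=int(k)) for c in comps]
    return out


def cluster_report(
    locations: dict[int, list[ClusterLocation]],
    dataset: ActivationDataset,
    factor_names: dict[int, str] | None = None,
) -> pd.DataFrame:
    """Flat table of cluster geometry: factor, region of centroid, centroid
    coordinates (mm), voxel count and radius."""
    rows = []
    for k, clusters in sorted(locations.items()):
        for loc in clusters:
            # region label of the voxel nearest the centroid
            d = np.linalg.norm(
                dataset.voxel_mm(loc.voxel_ids) - loc.centroid_mm, axis=1
            )
            nearest = loc.voxel_ids[int(np.argmin(d))]
            rows.append(
                {
                    "factor": factor_names.get(k, str(k)) if factor_names else k,
                    "region": str(dataset.region_labels[nearest]),
                    "x": loc.centroid_mm[0],
                    "y": loc.centroid_mm[1],
                    "z": loc.centroid_mm[2],
                    "n_voxels": loc.n_voxels,
                    "radius_mm": loc.radius_mm,
                }
            )
    return pd.DataFrame(
        rows, columns=["factor", "region", "x", "y", "z", "n_voxels", "radius_mm"]
    )
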