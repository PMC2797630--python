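"""On-disk dataset format: delimited text plus a JSON manifest.

A dataset directory contains ``manifest.json`` (shapes, geometry, seed and
config hash), ``voxels.tsv`` (id, grid indices, mm coordinates, region),
``words.tsv``, and one ``values_p{p}_r{r}.tsv`` words x voxels matrix per
participant and presentation. Everything is inspectable and diff-able;
NIfTI volumes are an optional export, not the internal format.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, is_dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .dataset import ActivationDataset

__all__ = ["save_dataset", "load_dataset", "export_nifti", "stability_table"]

_MANIFEST = "manifest.json"


def _config_hash(payload: dict) -> str:
    return hashlib.sha256(
        json.dumps(payload, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def save_dataset(
    dataset: ActivationDataset, path: str | Path, config=None, seed: int | None = None
) -> dict:
    """Write a dataset directory; returns the manifest dictionary."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    mm = dataset.voxel_mm()
    voxels = pd.DataFrame(
        {
            "voxel_id": np.arange(dataset.n_voxels),
            "i": dataset.voxel_coords[:, 0],
            "j": dataset.voxel_coords[:, 1],
            "k": dataset.voxel_coords[:, 2],
            "x_mm": mm[:, 0],
            "y_mm": mm[:, 1],
            "z_mm": mm[:, 2],
            "region": dataset.region_labels,
        }
    )
    voxels.to_csv(path / "voxels.tsv", sep="\t", index=False)
    pd.DataFrame({"word": dataset.words}).to_csv(
        path / "words.tsv", sep="\t", index=False
    )
    for p in range(dataset.n_participants):
        for r in range(dataset.n_presentations):
            np.savetxt(
                path / f"values_p{p}_r{r}.tsv",
                dataset.values[p, r],
                delimiter="\t",
                fmt="%.17g",  # full float64 precision for exact round-trips
            )
    config_payload = (
        asdict(config) if is_dataclass(config) else (config or {})
    )
    manifest = {
        "n_participants": dataset.n_participants,
        "n_presentations": dataset.n_presentations,
        "n_words": dataset.n_words,
        "n_voxels": dataset.n_voxels,
        "grid_dims": list(dataset.grid_dims),
        "voxel_size_mm": list(dataset.voxel_size_mm),
        "grid_origin_mm": list(dataset.grid_origin_mm),
        "seed": seed,
        "config": config_payload,
        "config_hash": _config_hash(config_payload),
    }
    (path / _MANIFEST).write_text(json.dumps(manifest, indent=2, default=str))
    return manifest


def load_dataset(path: str | Path) -> ActivationDataset:
    """Load and validate a dataset directory; errors name the missing piece."""
    path = Path(path)
    manifest_path = path / _MANIFEST
    if not manifest_path.exists():
        raise FileNotFoundError(f"missing {_MANIFEST} in {path}")
    manifest = json.loads(manifest_path.read_text())
    voxels_path = path / "voxels.tsv"
    if not voxels_path.exists():
        raise FileNotFoundError(f"missing voxels.tsv in {path}")
    voxels = pd.read_csv(voxels_path, sep="\t")
    words_path = path / "words.tsv"
    if not words_path.exists():
        raise FileNotFoundError(f"missing words.tsv in {path}")
    words = tuple(pd.read_csv(words_path, sep="\t")["word"].astype(str))
    if len(words) != manifest["n_words"]:
        raise ValueError(
            f"words.tsv has {len(words)} words, manifest says {manifest['n_words']}"
        )
    P, R = manifest["n_participants"], manifest["n_presentations"]
    values = np.empty((P, R, manifest["n_words"], manifest["n_voxels"]))
    for p in range(P):
        for r in range(R):
            f = path / f"values_p{p}_r{r}.tsv"
            if not f.exists():
                raise FileNotFoundError(f"missing {f.name} in {path}")
            mat = np.loadtxt(f, delimiter="\t", ndmin=2)
            if mat.shape != (manifest["n_words"], manifest["n_voxels"]):
                raise ValueError(
                    f"{f.name} has shape {mat.shape}, expected "
                    f"({manifest['n_words']}, {manifest['n_voxels']})"
                )
            values[p, r] = mat
    return ActivationDataset(
        values=values,
        voxel_coords=voxels[["i", "j", "k"]].to_numpy(),
        voxel_size_mm=tuple(manifest["voxel_size_mm"]),
        grid_origin_mm=tuple(manifest["grid_origin_mm"]),
        region_labels=voxels["region"].to_numpy(dtype=object),
        words=words,
        grid_dims=tuple(manifest["grid_dims"]),
    )


def export_nifti(
    dataset: ActivationDataset,
    per_voxel: np.ndarray,
    path: str | Path,
) -> None:
    """Write a per-voxel scalar map (stability, assignments, one word's image)
    as a NIfTI volume with the dataset's voxel size in the affine."""
    import nibabel as nib

    vol = np.zeros(dataset.grid_dims, dtype=float)
    vol[tuple(dataset.voxel_coords.T)] = np.asarray(per_voxel, dtype=float)
    affine = np.diag(list(dataset.voxel_size_mm) + [1.0])
    affine[:3, 3] = dataset.grid_origin_mm
    nib.save(nib.Nifti1Image(vol, affine), str(path))


def stability_table(dataset: ActivationDataset, scores: np.ndarray) -> pd.DataFrame:
    """Exportable per-voxel stability table with physical coordinates."""
    mm = dataset.voxel_mm()
    return pd.DataFrame(
        {
            "voxel_id": np.arange(dataset.n_voxels),
            "x_mm": mm[:, 0],
            "y_mm": mm[:, 1],
            "z_mm": mm[:, 2],
            "region": dataset.region_labels,
            "stability": np.asarray(scores, dtype=float),
        }
    )
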