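"""Run configuration: the pipeline's fixed constants in one place."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml


@dataclass
class RunConfig:
    """Parameters of the full pipeline, with the canonical defaults:
    50 stable voxels per lobe, 5 first-level and 10 second-level factors,
    a 0.4 loading-assignment threshold, 5 voxels per search volume for an
    80-voxel feature set, clusters of at least 5 voxels, and alpha 0.001
    for permutation / binomial chance thresholds."""

    n_stable_per_lobe: int = 50
    n_first_level_factors: int = 5
    n_second_level_factors: int = 10
    loading_threshold: float = 0.4
    per_volume_voxels: int = 5
    n_features: int = 80
    n_common_factors: int = 4
    min_cluster: int = 5
    connectivity: int = 26
    alpha: float = 0.001
    seed: int = 0
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in (
            "n_stable_per_lobe",
            "n_first_level_factors",
            "n_second_level_factors",
            "per_volume_voxels",
            "n_features",
            "n_common_factors",
            "min_cluster",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0 < self.loading_threshold < 1:
            raise ValueError("loading_threshold must be in (0, 1)")
        if self.connectivity not in (6, 18, 26):
            raise ValueError("connectivity must be 6, 18 or 26")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        extra = dict(data.pop("extra", {}))
        known = {k: v for k, v in data.items() if k in cls.__dataclass_fields__}
        extra.update(
            {k: v for k, v in data.items() if k not in cls.__dataclass_fields__}
        )
        return cls(**known, extra=extra)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))
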