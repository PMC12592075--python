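"""Typed run configuration with YAML round-trip.

Every stage parameter with an established default is a named field here:
the 95% intensity threshold, the 6000-voxel minimum object volume, the
100/230 μm zone bounds, the 5% COV gate, alpha = 0.05, the 0.31 μm pixel
and 0.85 μm slice spacing of the high-magnification geometry.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import yaml

__all__ = ["RunConfig"]


@dataclass
class RunConfig:
    out_dir: str = "cordmorph_out"
    seed: int = 0

    # imaging geometry (μm)
    pixel_size_um: float = 0.31
    slice_spacing_um: float = 0.85

    # canal segmentation
    min_component_px: int = 200

    # cell detection
    threshold_fraction: float = 0.95
    min_voxels: int = 6000
    connectivity: int = 3  # 26-neighbour adjacency
    z_window: int = 2
    zone_bounds_um: tuple[float, float] = (100.0, 230.0)

    # morphometry / statistics
    cov_threshold_percent: float = 5.0
    alpha: float = 0.05
    commissure_definition: str = "half_sum"
    equal_var_ttest: bool = True

    # simulation scale (synthetic demo inputs)
    simulate: bool = True
    image_shape: tuple[int, int] = (256, 256)
    n_slices: int = 16  # a 6000-voxel cell spans ~12 slices at 0.85 um spacing
    n_cells: int = 8
    cell_volume_voxels: int = 6000
    cohort_animals_per_cell: int = 2
    cohort_sections_per_segment: int = 22
    cohort_age_effect_ap_um: float = -100.0

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        cfg = cls(**data)
        # YAML has no tuple type; normalize list-valued fields
        cfg.zone_bounds_um = tuple(cfg.zone_bounds_um)
        cfg.image_shape = tuple(cfg.image_shape)
        return cfg

    def to_yaml(self, path) -> None:
        data = self.to_dict()
        data["zone_bounds_um"] = list(data["zone_bounds_um"])
        data["image_shape"] = list(data["image_shape"])
        Path(path).write_text(yaml.safe_dump(data, sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    @property
    def config_hash(self) -> str:
        data = self.to_dict()
        data["zone_bounds_um"] = list(data["zone_bounds_um"])
        data["image_shape"] = list(data["image_shape"])
        return hashlib.sha256(
            json.dumps(data, sort_keys=True).encode()
        ).hexdigest()[:16]
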