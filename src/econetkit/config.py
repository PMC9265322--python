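"""Pipeline configuration with built-in study defaults.

Defaults reproduce the published workflow settings: foreground classes
{paddy field, woodland, grassland, water area, bottomland}; dispersal
distance thresholds 100/500/1000/1500/2000 m with connection probability 0.5
at the threshold; source selection at dPC > 1; corridor minimum length 10 km;
gravity tier bounds 1/10/100; resistance grading tables and AHP layer weights
(0.5638 MSPA, 0.2634 land cover, 0.1178 elevation, 0.055 slope).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

__all__ = [
    "LAND_CLASSES",
    "ResistanceConfig",
    "PipelineConfig",
    "load_config",
    "save_config",
]

# Land-cover legend: code -> class name (8 classes)
LAND_CLASSES: dict[int, str] = {
    1: "paddy field",
    2: "dry land",
    3: "woodland",
    4: "grassland",
    5: "water area",
    6: "bottomland",
    7: "construction land",
    8: "unutilized land",
}

_FOREGROUND_DEFAULT = frozenset({1, 3, 4, 5, 6})  # paddy, wood, grass, water, bottomland

# MSPA class codes used throughout
MSPA_CODES: dict[str, int] = {
    "background": 0,
    "core": 1,
    "islet": 2,
    "edge": 3,
    "bridge": 4,
    "branch": 5,
    "loop": 6,
    "perforation": 7,
}


@dataclass
class ResistanceConfig:
    """Graded resistance coefficients and AHP layer weights.

    Coefficients are on a 1-100 ladder; higher resists ecological flow more.
    """

    mspa_coefficients: dict[str, float] = field(default_factory=lambda: {
        "core": 10, "islet": 10,
        "edge": 20, "bridge": 20,
        "branch": 30, "loop": 30,
        "perforation": 40,
        "background": 80,
    })
    landcover_coefficients: dict[int, float] = field(default_factory=lambda: {
        1: 40,   # paddy field
        2: 50,   # dry land
        3: 10,   # woodland
        4: 20,   # grassland
        5: 30,   # water area
        6: 30,   # bottomland
        7: 100,  # construction land
        8: 60,   # unutilized land
    })
    # breaks are upper bounds of the first k-1 classes; coefficients has k entries
    elevation_breaks: tuple[float, ...] = (150.0, 300.0, 600.0, 1000.0)
    elevation_coefficients: tuple[float, ...] = (10, 20, 40, 70, 90)
    slope_breaks: tuple[float, ...] = (5.0, 10.0, 30.0, 45.0)
    slope_coefficients: tuple[float, ...] = (10, 20, 40, 60, 80)
    # AHP weights: MSPA, land cover, elevation, slope
    weights: tuple[float, ...] = (0.5638, 0.2634, 0.1178, 0.055)
    classing_mode: str = "fixed_breaks"  # or "natural_breaks"

    def validate(self) -> None:
        all_coeff = (
            list(self.mspa_coefficients.values())
            + list(self.landcover_coefficients.values())
            + list(self.elevation_coefficients)
            + list(self.slope_coefficients)
        )
        if any(c < 1 or c > 100 for c in all_coeff):
            raise ValueError("resistance coefficients must lie in [1, 100]")
        if any(w <= 0 for w in self.weights):
            raise ValueError("layer weights must be positive")
        if abs(sum(self.weights) - 1.0) > 1e-6:
            raise ValueError(f"layer weights must sum to 1, got {sum(self.weights)}")
        if self.classing_mode not in {"fixed_breaks", "natural_breaks"}:
            raise ValueError(f"unknown classing mode {self.classing_mode!r}")


@dataclass
class PipelineConfig:
    """End-to-end pipeline settings; defaults reproduce the study's printed values."""

    foreground_classes: frozenset[int] = _FOREGROUND_DEFAULT
    mspa_edge_width_cells: int = 1
    mspa_connectivity: int = 8
    min_core_area_cells: int = 10
    thresholds_m: tuple[float, ...] = (100.0, 500.0, 1000.0, 1500.0, 2000.0)
    optimal_threshold_m: float = 1000.0
    connectivity_probability: float = 0.5
    min_dpc: float = 1.0
    resistance: ResistanceConfig = field(default_factory=ResistanceConfig)
    corridor_min_length_km: float = 10.0
    corridor_dedup_overlap: float = 0.9
    gravity_tier_bounds: tuple[float, float, float] = (1.0, 10.0, 100.0)
    gravity_area_unit: str = "ha"
    hydrology_quantile: float = 0.95
    node_merge_radius_cells: int = 3
    seed: int = 0

    def validate(self) -> None:
        if not self.foreground_classes:
            raise ValueError("foreground_classes must be non-empty")
        if self.mspa_edge_width_cells < 1:
            raise ValueError("mspa_edge_width_cells must be >= 1")
        if self.mspa_connectivity not in (4, 8):
            raise ValueError("mspa_connectivity must be 4 or 8")
        if not 0 < self.connectivity_probability < 1:
            raise ValueError("connectivity_probability must lie in (0, 1)")
        if not 0 < self.hydrology_quantile < 1:
            raise ValueError("hydrology_quantile must lie in (0, 1)")
        b = self.gravity_tier_bounds
        if not (b[0] < b[1] < b[2]):
            raise ValueError("gravity tier bounds must be strictly increasing")
        self.resistance.validate()

    def to_dict(self) -> dict:
        d = asdict(self)
        d["foreground_classes"] = sorted(self.foreground_classes)
        return d


def _cfg_from_dict(d: dict) -> PipelineConfig:
    d = dict(d)
    if "foreground_classes" in d:
        d["foreground_classes"] = frozenset(d["foreground_classes"])
    if "resistance" in d and isinstance(d["resistance"], dict):
        r = dict(d["resistance"])
        for key in ("elevation_breaks", "elevation_coefficients",
                    "slope_breaks", "slope_coefficients", "weights"):
            if key in r:
                r[key] = tuple(r[key])
        if "landcover_coefficients" in r:
            r["landcover_coefficients"] = {int(k): v for k, v in r["landcover_coefficients"].items()}
        d["resistance"] = ResistanceConfig(**r)
    for key in ("thresholds_m", "gravity_tier_bounds"):
        if key in d:
            d[key] = tuple(d[key])
    return PipelineConfig(**d)


def load_config(path: str | Path) -> PipelineConfig:
    """Load a YAML pipeline config; missing keys fall back to study defaults."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    cfg = _cfg_from_dict(data)
    cfg.validate()
    return cfg


def save_config(cfg: PipelineConfig, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        yaml.safe_dump(cfg.to_dict(), fh, sort_keys=True)
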