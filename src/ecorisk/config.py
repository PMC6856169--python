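"""Region-generator configuration and validation."""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Tuple


class ConfigError(ValueError):
    """Raised when a configuration field is invalid; names the field."""


# class means of the continuous layers, keyed by land-cover code
# (see landcover.CLASS_CODES order: forest, grassland, wetland, farmland,
# artificial, bare)
_DEFAULT_NPP = {1: 0.60, 2: 0.35, 3: 0.40, 4: 0.45, 5: 0.10, 6: 0.05}  # kg C/m2
_DEFAULT_EVI = {1: 0.45, 2: 0.30, 3: 0.35, 4: 0.38, 5: 0.12, 6: 0.08}  # unitless
_DEFAULT_ET = {1: 0.45, 2: 0.30, 3: 0.55, 4: 0.35, 5: 0.05, 6: 0.03}  # m/yr
_DEFAULT_LST_OFFSET = {1: 0.0, 2: 0.3, 3: -0.5, 4: 0.5, 5: 3.0, 6: 2.0}  # K


@dataclass
class RegionConfig:
    """Parameters of the synthetic two-epoch regional dataset.

    Distances are kilometres; each grid cell is ``cell_area`` square metres
    (square cells). Cell centres sit at ``(row + 0.5, col + 0.5)`` times the
    cell size, row-major and north-up.
    """

    grid_rows: int = 110
    grid_cols: int = 119
    cell_area: float = 16_000_000.0  # m2 (4 km cells; region ~ 440 x 476 km)
    n_units: int = 187
    epochs: Tuple[str, str] = ("t0", "t1")
    urban_core_centers: List[Tuple[float, float]] = field(
        default_factory=lambda: [(32.0, 42.0), (66.0, 80.0)]
    )
    dn_max: float = 63.0
    dn_decay: float = 100.0  # e-folding distance (km) of the DN surface at t0
    dn_growth: float = 2.2  # multiplier on dn_decay at t1 (urban expansion)
    artificial_dn_threshold: float = 50.0  # noise-free DN above which t0 is built-up
    artificial_delta: float = 0.0103  # fraction of cells converted t0 -> t1
    veg_decline: float = 0.9  # t1 multiplier on NPP/EVI/ET class means
    climate_gradient: float = 0.4  # fractional N-S productivity trend (peak-to-peak)
    lst_trend: float = 2.0  # K peak-to-peak N-S temperature trend
    noise_sd: Dict[str, float] = field(
        default_factory=lambda: {
            "dn": 2.0,
            "npp": 0.03,
            "evi": 0.02,
            "et": 0.03,
            "lst": 0.5,
        }
    )
    lst_base: float = 300.0  # K, summer reference
    npp_class_mean: Dict[int, float] = field(default_factory=lambda: dict(_DEFAULT_NPP))
    evi_class_mean: Dict[int, float] = field(default_factory=lambda: dict(_DEFAULT_EVI))
    et_class_mean: Dict[int, float] = field(default_factory=lambda: dict(_DEFAULT_ET))
    lst_class_offset: Dict[int, float] = field(
        default_factory=lambda: dict(_DEFAULT_LST_OFFSET)
    )
    seed: int = 20190
    validate_on_init: bool = True

    def __post_init__(self) -> None:
        if self.validate_on_init:
            self.validate()

    @property
    def cell_size_km(self) -> float:
        return math.sqrt(self.cell_area) / 1000.0

    @property
    def n_cells(self) -> int:
        return self.grid_rows * self.grid_cols

    def validate(self) -> None:
        if self.grid_rows < 1:
            raise ConfigError("grid_rows must be a positive integer")
        if self.grid_cols < 1:
            raise ConfigError("grid_cols must be a positive integer")
        if self.cell_area <= 0:
            raise ConfigError("cell_area must be positive")
        if self.n_units < 1:
            raise ConfigError("n_units must be a positive integer")
        if self.n_units > self.n_cells:
            raise ConfigError(
                f"n_units ({self.n_units}) exceeds grid cells ({self.n_cells})"
            )
        if len(self.epochs) != 2:
            raise ConfigError("epochs must contain exactly two labels")
        if not self.urban_core_centers:
            raise ConfigError("urban_core_centers must list at least one center")
        if not 0 <= self.artificial_delta < 1:
            raise ConfigError("artificial_delta must lie in [0, 1)")
        if not 0 < self.dn_max <= 63:
            raise ConfigError("dn_max must lie in (0, 63]")
        if self.dn_decay <= 0:
            raise ConfigError("dn_decay must be positive")
        if self.dn_growth < 1:
            raise ConfigError("dn_growth must be >= 1 (cores do not shrink)")
        for name, sd in self.noise_sd.items():
            if sd < 0:
                raise ConfigError(f"noise_sd[{name!r}] must be >= 0")
        if not 0 < self.veg_decline <= 1.5:
            raise ConfigError("veg_decline must lie in (0, 1.5]")
        if not 0 <= self.climate_gradient < 2:
            raise ConfigError("climate_gradient must lie in [0, 2)")
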