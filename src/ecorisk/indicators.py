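"""Six ecological status indicators per assessing unit.

NPP, EVI and ET are zonal means of (temporally composited) satellite-style
layers; the curve number comes from a land-cover x hydrologic-soil-group
lookup (TR-55-style defaults shipped as an editable CSV); carbon
sequestration capacity from a per-class lookup; local climate regulation is
the ratio of a unit's mean summer land-surface temperature to the regional
mean over vegetated cells.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from importlib import resources
from typing import Dict, Optional, Tuple

import numpy as np
import pandas as pd

from .landcover import (
    CLASS_CODES,
    CLASS_NAMES,
    NAME_TO_CODE,
    SOIL_CODE,
    SOIL_GROUPS,
    SOIL_NAME,
    VEGETATED,
)
from .synthetic import RegionDataset, UnitPartition

log = logging.getLogger(__name__)

INDICATOR_COLUMNS = ("npp", "evi", "et", "cn", "carbon", "lcr")


class LookupError_(KeyError):
    """A (class, soil group) or class key missing from a lookup table."""


def _default_path(name: str):
    return resources.files("ecorisk.data") / name


# ---------------------------------------------------------------------------
# Lookup tables
# ---------------------------------------------------------------------------


@dataclass
class CNLookup:
    """Curve numbers by (land-cover class, hydrologic soil group A-D)."""

    table: Dict[Tuple[int, str], float]

    def __post_init__(self) -> None:
        for code in CLASS_CODES:
            for g in SOIL_GROUPS:
                if (code, g) not in self.table:
                    raise LookupError_(
                        f"CN table missing ({CLASS_NAMES[code]}, {g})"
                    )
        for (code, g), cn in self.table.items():
            if not 30 <= cn <= 100:
                raise ValueError(
                    f"CN({CLASS_NAMES[code]}, {g}) = {cn} outside [30, 100]"
                )
        from .landcover import ARTIFICIAL, FOREST

        for g in SOIL_GROUPS:
            if self.table[(ARTIFICIAL, g)] < self.table[(FOREST, g)]:
                raise ValueError(
                    f"CN(artificial, {g}) < CN(forest, {g}): runoff ordering violated"
                )

    @classmethod
    def from_csv(cls, path=None) -> "CNLookup":
        path = path or _default_path("cn_lookup.csv")
        df = pd.read_csv(path)
        for col in ("class", "group", "cn"):
            if col not in df.columns:
                raise ValueError(f"CN lookup CSV missing required column {col!r}")
        table = {
            (NAME_TO_CODE[r["class"]], r["group"]): float(r["cn"])
            for _, r in df.iterrows()
        }
        return cls(table)

    def lookup(self, class_code: int, group: str) -> float:
        key = (class_code, group)
        if key not in self.table:
            name = CLASS_NAMES.get(class_code, f"code {class_code}")
            raise LookupError_(f"no CN entry for ({name}, {group})")
        return self.table[key]


@dataclass
class CarbonLookup:
    """Carbon sequestration capacity (g C/m2) by land-cover class."""

    table: Dict[int, float]

    def __post_init__(self) -> None:
        from .landcover import ARTIFICIAL

        for code in CLASS_CODES:
            if code not in self.table:
                raise LookupError_(f"carbon table missing class {CLASS_NAMES[code]}")
        if any(v < 0 for v in self.table.values()):
            raise ValueError("carbon capacities must be nonnegative")
        art = self.table[ARTIFICIAL]
        for code in VEGETATED:
            if art > self.table[code]:
                raise ValueError(
                    "carbon(artificial) exceeds a vegetated class capacity"
                )

    @classmethod
    def from_csv(cls, path=None) -> "CarbonLookup":
        path = path or _default_path("carbon_lookup.csv")
        df = pd.read_csv(path)
        for col in ("class", "gC_m2"):
            if col not in df.columns:
                raise ValueError(f"carbon lookup CSV missing required column {col!r}")
        return cls({NAME_TO_CODE[r["class"]]: float(r["gC_m2"]) for _, r in df.iterrows()})


# ---------------------------------------------------------------------------
# Layer operations
# ---------------------------------------------------------------------------


def temporal_composite(stack: np.ndarray, statistic: str = "mean") -> np.ndarray:
    """Cellwise composite of a (k, rows, cols) stack, ignoring NaN nodata.

    A cell that is nodata in every layer stays NaN.
    """
    if statistic != "mean":
        raise ValueError(f"unsupported composite statistic {statistic!r}")
    arr = np.asarray(stack, dtype=float)
    if arr.ndim == 2:
        arr = arr[None, ...]
    if arr.shape[0] == 0:
        raise ValueError("empty stack: nothing to composite")
    import warnings

    with np.errstate(invalid="ignore"), warnings.catch_warnings():
        # all-nodata cells legitimately yield NaN; silence the empty-slice note
        warnings.filterwarnings("ignore", message="Mean of empty slice")
        out = np.nanmean(arr, axis=0)
    return out


def curve_number_layer(
    land_cover: np.ndarray, soil_group: np.ndarray, table: CNLookup
) -> np.ndarray:
    """Cellwise CN lookup from land cover and soil-group grids."""
    if land_cover.shape != soil_group.shape:
        raise ValueError("land cover and soil group grids differ in shape")
    out = np.empty(land_cover.shape, dtype=float)
    for code in np.unique(land_cover):
        for gcode in np.unique(soil_group):
            g = SOIL_NAME.get(int(gcode))
            if g is None:
                raise LookupError_(f"unknown soil-group code {int(gcode)}")
            sel = (land_cover == code) & (soil_group == gcode)
            if sel.any():
                out[sel] = table.lookup(int(code), g)
    return out


def carbon_layer(land_cover: np.ndarray, table: CarbonLookup) -> np.ndarray:
    """Cellwise carbon sequestration capacity from land cover."""
    out = np.empty(land_cover.shape, dtype=float)
    for code in np.unique(land_cover):
        if int(code) not in table.table:
            raise LookupError_(f"no carbon entry for land-cover code {int(code)}")
        out[land_cover == code] = table.table[int(code)]
    return out


def zonal_mean(layer: np.ndarray, partition: UnitPartition) -> np.ndarray:
    """Mean of non-nodata member cells per unit (vector indexed unit-1).

    A unit whose cells are all nodata yields NaN and is reported in the log.
    """
    if layer.shape != partition.unit_id.shape:
        raise ValueError("layer and partition grids differ in shape")
    vals = np.asarray(layer, dtype=float).ravel()
    lab = partition.unit_id.ravel()
    ok = ~np.isnan(vals)
    n = partition.n_units
    sums = np.bincount(lab[ok], weights=vals[ok], minlength=n + 1)[1:]
    counts = np.bincount(lab[ok], minlength=n + 1)[1:]
    out = np.full(n, np.nan)
    nz = counts > 0
    out[nz] = sums[nz] / counts[nz]
    if (~nz).any():
        log.warning("%d unit(s) with no valid cells in zonal mean", int((~nz).sum()))
    return out


def local_climate_regulation(
    summer_lst_mean: np.ndarray,
    land_cover: np.ndarray,
    partition: UnitPartition,
) -> np.ndarray:
    """LCR per unit: unit mean LST over the regional vegetated-cell mean LST.

    Values above 1 indicate local warming relative to vegetation. The
    reference mean pools all vegetated cells (forest, grassland, wetland,
    farmland) of the whole region.
    """
    veg = np.isin(land_cover, VEGETATED)
    if not veg.any():
        raise ValueError("no vegetated cells: LCR reference undefined")
    ref = float(np.nanmean(summer_lst_mean[veg]))
    return zonal_mean(summer_lst_mean, partition) / ref


# ---------------------------------------------------------------------------
# Indicator table
# ---------------------------------------------------------------------------


def compute_indicator_table(
    region: RegionDataset,
    cn_table: Optional[CNLookup] = None,
    carbon_table: Optional[CarbonLookup] = None,
) -> pd.DataFrame:
    """All six status indicators per unit and epoch (tidy DataFrame).

    Columns: unit_id, epoch, npp, evi, et, cn, carbon, lcr.
    """
    cn_table = cn_table or CNLookup.from_csv()
    carbon_table = carbon_table or CarbonLookup.from_csv()
    part = region.partition
    frames = []
    for e in region.epochs:
        lc = region.land_cover[e]
        evi_annual = temporal_composite(region.evi[e])
        lst_summer = temporal_composite(region.lst[e])
        row = {
            "unit_id": np.arange(1, part.n_units + 1),
            "epoch": e,
            "npp": zonal_mean(region.npp[e], part),
            "evi": zonal_mean(evi_annual, part),
            "et": zonal_mean(region.et[e], part),
            "cn": zonal_mean(curve_number_layer(lc, region.soil_group, cn_table), part),
            "carbon": zonal_mean(carbon_layer(lc, carbon_table), part),
            "lcr": local_climate_regulation(lst_summer, lc, part),
        }
        frames.append(pd.DataFrame(row))
    out = pd.concat(frames, ignore_index=True)
    if out[list(INDICATOR_COLUMNS)].isna().any().any():
        raise ValueError("missing indicator values after computation")
    return out
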