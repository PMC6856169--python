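"""Ecosystem service values by the benefit-transfer (value-coefficient) method.

Per assessing unit and service category, ESV = sum_k A_k * VC_k where A_k is
the member area of land-cover class k (m2) and VC_k its monetary coefficient
(Yuan/m2). The default coefficient table is synthetic, with category
magnitudes in the 0.005-2.5 Yuan/m2 range typical of published Chinese
benefit-transfer tables, and is fully replaceable via CSV.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Dict, Tuple

import numpy as np
import pandas as pd

from .gradient import GRADIENT_NAMES
from .landcover import (
    ARTIFICIAL,
    CLASS_CODES,
    CLASS_NAMES,
    NAME_TO_CODE,
    SERVICE_CATEGORIES,
    VEGETATED,
)
from .synthetic import UnitPartition


class ServiceError(ValueError):
    pass


@dataclass
class ValueCoefficientTable:
    """(land-cover class, category) -> Yuan/m2 value coefficients."""

    table: Dict[Tuple[int, str], float]

    def __post_init__(self) -> None:
        for code in CLASS_CODES:
            for cat in SERVICE_CATEGORIES:
                if (code, cat) not in self.table:
                    raise ServiceError(
                        f"value coefficients missing ({CLASS_NAMES[code]}, {cat})"
                    )
        if any(v < 0 for v in self.table.values()):
            raise ServiceError("value coefficients must be nonnegative")
        for cat in SERVICE_CATEGORIES:
            art = self.table[(ARTIFICIAL, cat)]
            for code in VEGETATED:
                if art > self.table[(code, cat)]:
                    raise ServiceError(
                        f"VC(artificial, {cat}) exceeds VC({CLASS_NAMES[code]}, {cat})"
                    )

    @classmethod
    def from_csv(cls, path=None) -> "ValueCoefficientTable":
        path = path or resources.files("ecorisk.data") / "value_coefficients.csv"
        df = pd.read_csv(path)
        for col in ("class", "category", "yuan_per_m2"):
            if col not in df.columns:
                raise ServiceError(
                    f"value coefficient CSV missing required column {col!r}"
                )
        return cls(
            {
                (NAME_TO_CODE[r["class"]], r["category"]): float(r["yuan_per_m2"])
                for _, r in df.iterrows()
            }
        )

    def scaled(self, factor: float) -> "ValueCoefficientTable":
        return ValueCoefficientTable({k: v * factor for k, v in self.table.items()})


def esv_by_unit(
    land_cover: np.ndarray,
    partition: UnitPartition,
    table: ValueCoefficientTable,
    cell_area: float,
) -> pd.DataFrame:
    """Per-unit ecosystem service values and per-area densities.

    Returns a DataFrame with one row per unit: unit_id, area_m2, per
    category the value in Yuan (``<cat>_yuan``) and density in Yuan/m2
    (``<cat>_density``), plus totals.
    """
    if land_cover.shape != partition.unit_id.shape:
        raise ServiceError("land cover and partition grids differ in shape")
    present = [int(c) for c in np.unique(land_cover)]
    for code in present:
        if (code, SERVICE_CATEGORIES[0]) not in table.table:
            name = CLASS_NAMES.get(code, f"code {code}")
            raise ServiceError(f"land-cover class {name} missing from coefficient table")
    lab = partition.unit_id.ravel()
    lc = land_cover.ravel()
    n = partition.n_units
    out = pd.DataFrame(
        {"unit_id": np.arange(1, n + 1), "area_m2": partition.areas_m2}
    )
    # member area of class k within each unit
    area_k = {
        code: np.bincount(lab[lc == code], minlength=n + 1)[1:] * cell_area
        for code in present
    }
    total = np.zeros(n)
    for cat in SERVICE_CATEGORIES:
        val = np.zeros(n)
        for code in present:
            val += area_k[code] * table.table[(code, cat)]
        out[f"{cat}_yuan"] = val
        out[f"{cat}_density"] = val / out["area_m2"]
        total += val
    out["total_yuan"] = total
    out["total_density"] = total / out["area_m2"]
    return out


def esv_table(
    region, table: ValueCoefficientTable = None
) -> pd.DataFrame:
    """ESV per unit for both epochs of a region dataset (tidy, epoch column)."""
    table = table or ValueCoefficientTable.from_csv()
    frames = []
    for e in region.epochs:
        df = esv_by_unit(
            region.land_cover[e], region.partition, table, region.config.cell_area
        )
        df.insert(1, "epoch", e)
        frames.append(df)
    return pd.concat(frames, ignore_index=True)


def esv_gradient_profile(
    service: pd.DataFrame, classes: np.ndarray
) -> pd.DataFrame:
    """Mean service density per gradient class and category.

    ``service`` is the per-unit frame of :func:`esv_by_unit` (single epoch);
    ``classes`` the per-unit gradient codes. Returns rows (class, category,
    mean_density, n); classes with no units are omitted.
    """
    if len(service) != len(classes):
        raise ServiceError("service table and gradient classes are not aligned")
    rows = []
    for code, name in GRADIENT_NAMES.items():
        sel = np.asarray(classes) == code
        if not sel.any():
            continue
        for cat in SERVICE_CATEGORIES + ("total",):
            rows.append(
                {
                    "gradient": name,
                    "category": cat,
                    "mean_density": float(service.loc[sel, f"{cat}_density"].mean()),
                    "n": int(sel.sum()),
                }
            )
    return pd.DataFrame(rows)
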