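"""Pressure-status-response composites with entropy weighting.

Twelve per-unit indicators — two pressure (unit-mean nighttime-light DN and
artificial-surface ratio), six status (NPP, EVI, ET, CN, carbon, LCR) and
four response (the ecosystem-service category densities) — are min-max
normalised according to their attribute direction, pooled over both epochs
so composites are comparable between years. Status and response composites
use entropy weights; the pressure composite uses equal weights on its two
indicators.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from importlib import resources
from typing import Dict, List, Sequence

import numpy as np
import pandas as pd
from scipy import stats

BLOCKS = ("pressure", "status", "response")


class PSRError(ValueError):
    pass


@dataclass(frozen=True)
class IndicatorSpec:
    name: str
    block: str  # pressure | status | response
    attribute: str  # positive | negative

    def __post_init__(self) -> None:
        if self.block not in BLOCKS:
            raise PSRError(f"unknown block {self.block!r} for {self.name}")
        if self.attribute not in ("positive", "negative"):
            raise PSRError(f"unknown attribute {self.attribute!r} for {self.name}")


def load_indicator_specs(path=None) -> List[IndicatorSpec]:
    """Read indicator specs from CSV (name, block, attribute)."""
    path = path or resources.files("ecorisk.data") / "indicator_spec.csv"
    df = pd.read_csv(path)
    for col in ("name", "block", "attribute"):
        if col not in df.columns:
            raise PSRError(f"indicator spec CSV missing required column {col!r}")
    return [IndicatorSpec(r["name"], r["block"], r["attribute"]) for _, r in df.iterrows()]


def default_specs() -> List[IndicatorSpec]:
    specs = load_indicator_specs()
    blocks = {b: [s for s in specs if s.block == b] for b in BLOCKS}
    if (len(blocks["pressure"]), len(blocks["status"]), len(blocks["response"])) != (
        2,
        6,
        4,
    ):
        raise PSRError("default spec must define 2 pressure, 6 status, 4 response")
    return specs


def minmax_normalize(
    matrix: np.ndarray, specs: Sequence[IndicatorSpec]
) -> np.ndarray:
    """Column-wise min-max normalisation respecting attribute direction.

    Positive attribute: (x - min) / (max - min); negative: (max - x) /
    (max - min). A constant column maps to 0.5 everywhere (neutral) with a
    warning.
    """
    X = np.asarray(matrix, dtype=float)
    if X.ndim != 2 or X.shape[1] != len(specs):
        raise PSRError("matrix columns do not match indicator specs")
    if not np.all(np.isfinite(X)):
        raise PSRError("non-finite values in indicator matrix")
    out = np.empty_like(X)
    for j, spec in enumerate(specs):
        col = X[:, j]
        lo, hi = col.min(), col.max()
        if hi == lo:
            warnings.warn(
                f"indicator {spec.name!r} is constant; normalised to 0.5",
                stacklevel=2,
            )
            out[:, j] = 0.5
        elif spec.attribute == "positive":
            out[:, j] = (col - lo) / (hi - lo)
        else:
            out[:, j] = (hi - col) / (hi - lo)
    return out


def entropy_weights(normalized: np.ndarray) -> np.ndarray:
    """Entropy weights over columns of a normalised (n x m) matrix.

    p_ij = x_ij / sum_i x_ij (uniform if the column sums to zero);
    e_j = -(1/ln n) sum_i p_ij ln p_ij with 0 ln 0 = 0;
    w_j = (1 - e_j) / sum_k (1 - e_k), equal weights if every e_j = 1.
    """
    X = np.asarray(normalized, dtype=float)
    if X.ndim != 2:
        raise PSRError("expected a 2-D matrix")
    n, m = X.shape
    if n < 2:
        raise PSRError("entropy weights need at least 2 rows")
    if X.min() < 0 or X.max() > 1:
        raise PSRError("entropy weights expect entries in [0, 1]")
    e = np.empty(m)
    for j in range(m):
        col = X[:, j]
        s = col.sum()
        p = np.full(n, 1.0 / n) if s == 0 else col / s
        with np.errstate(divide="ignore", invalid="ignore"):
            plogp = np.where(p > 0, p * np.log(p), 0.0)
        e[j] = -plogp.sum() / np.log(n)
    d = 1.0 - e
    total = d.sum()
    if total <= 0:
        return np.full(m, 1.0 / m)
    return d / total


def composite(normalized: np.ndarray, weights: np.ndarray) -> np.ndarray:
    """Weighted-sum composite score per row; stays in [0, 1]."""
    X = np.asarray(normalized, dtype=float)
    w = np.asarray(weights, dtype=float)
    if X.shape[1] != w.shape[0]:
        raise PSRError("weights length does not match matrix columns")
    if np.any(w < 0) or not np.isclose(w.sum(), 1.0):
        raise PSRError("weights must be nonnegative and sum to 1")
    return X @ w


def assemble_psr(
    indicators: pd.DataFrame,
    services: pd.DataFrame,
    pressure: pd.DataFrame,
    specs: Sequence[IndicatorSpec] = None,
) -> Dict[str, object]:
    """Build pressure/status/response composites per unit and epoch.

    Parameters
    ----------
    indicators : tidy frame (unit_id, epoch, npp, evi, et, cn, carbon, lcr)
    services : tidy frame with unit_id, epoch and ``<cat>_density`` columns
    pressure : tidy frame (unit_id, epoch, mean_dn, artificial_ratio)
    specs : the 12 indicator specs (default CSV)

    Normalisation pools both epochs; entropy weights are computed on the
    pooled status and response blocks; pressure uses equal weights.

    Returns a dict with the PSR table (unit_id, epoch, pressure, status,
    response), the pooled normalised matrix, and the weight vectors.
    """
    specs = list(specs) if specs is not None else default_specs()
    svc = services.copy()
    rename = {
        f"{c}_density": f"esv_{c}"
        for c in ("provisioning", "supporting", "regulating", "cultural")
    }
    svc = svc.rename(columns=rename)
    merged = pressure.merge(indicators, on=["unit_id", "epoch"], how="inner").merge(
        svc[["unit_id", "epoch", *rename.values()]], on=["unit_id", "epoch"], how="inner"
    )
    names = [s.name for s in specs]
    missing = [n for n in names if n not in merged.columns]
    if missing:
        raise PSRError(f"missing indicator(s): {', '.join(missing)}")
    merged = merged.sort_values(["epoch", "unit_id"]).reset_index(drop=True)
    X = merged[names].to_numpy(dtype=float)
    norm = minmax_normalize(X, specs)

    idx = {b: [j for j, s in enumerate(specs) if s.block == b] for b in BLOCKS}
    w_pressure = np.full(len(idx["pressure"]), 1.0 / len(idx["pressure"]))
    w_status = entropy_weights(norm[:, idx["status"]])
    w_response = entropy_weights(norm[:, idx["response"]])

    psr = merged[["unit_id", "epoch"]].copy()
    psr["pressure"] = composite(norm[:, idx["pressure"]], w_pressure)
    psr["status"] = composite(norm[:, idx["status"]], w_status)
    psr["response"] = composite(norm[:, idx["response"]], w_response)
    return {
        "psr": psr,
        "normalized": pd.DataFrame(norm, columns=names).assign(
            unit_id=merged["unit_id"], epoch=merged["epoch"]
        ),
        "weights": {
            "pressure": dict(zip([names[j] for j in idx["pressure"]], w_pressure)),
            "status": dict(zip([names[j] for j in idx["status"]], w_status)),
            "response": dict(zip([names[j] for j in idx["response"]], w_response)),
        },
    }


def pressure_inputs(region) -> pd.DataFrame:
    """Unit-mean DN and artificial-surface ratio per unit and epoch."""
    from .indicators import zonal_mean
    from .landcover import ARTIFICIAL

    part = region.partition
    frames = []
    for e in region.epochs:
        frames.append(
            pd.DataFrame(
                {
                    "unit_id": np.arange(1, part.n_units + 1),
                    "epoch": e,
                    "mean_dn": zonal_mean(region.dn[e].astype(float), part),
                    "artificial_ratio": zonal_mean(
                        (region.land_cover[e] == ARTIFICIAL).astype(float), part
                    ),
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def pearson_matrix(
    psr: pd.DataFrame, indicators: pd.DataFrame, epoch: str = None
) -> pd.DataFrame:
    """Pearson r (with two-sided t-based p) between composites and indicators.

    Rows: (composite, indicator, r, p). Zero-variance vectors yield NaN r
    with a flag column set.
    """
    df = psr.merge(indicators, on=["unit_id", "epoch"], how="inner")
    if epoch is not None:
        df = df[df["epoch"] == epoch]
    if len(df) < 3:
        raise PSRError("need at least 3 aligned units for correlation")
    from .indicators import INDICATOR_COLUMNS

    rows = []
    for comp in BLOCKS:
        for ind in INDICATOR_COLUMNS:
            x = df[comp].to_numpy(float)
            y = df[ind].to_numpy(float)
            if x.std() == 0 or y.std() == 0:
                rows.append(
                    {"composite": comp, "indicator": ind, "r": np.nan, "p": np.nan,
                     "degenerate": True}
                )
                continue
            r, p = stats.pearsonr(x, y)
            rows.append(
                {"composite": comp, "indicator": ind, "r": float(r), "p": float(p),
                 "degenerate": False}
            )
    return pd.DataFrame(rows)
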