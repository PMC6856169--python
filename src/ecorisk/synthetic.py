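"""Seeded synthetic regional datasets.

The generator emulates the data structure of a two-epoch urbanising region:
an urban core (or several) whose nighttime-light DN surface decays with
distance and brightens between epochs, land cover with an expanding
artificial-surface footprint, continuous vegetation/climate layers whose
class means are tied to land cover, a hydrologic-soil-group map, and a
partition of the grid into contiguous assessing units.

It also provides a Gibbs sampler for binary autologistic fields on an
arbitrary neighbour structure, used to validate the maximum
pseudo-likelihood estimator.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional

import numpy as np
from scipy.ndimage import gaussian_filter

from .config import ConfigError, RegionConfig
from .landcover import (
    ARTIFICIAL,
    BARE,
    FARMLAND,
    FOREST,
    GRASSLAND,
    WETLAND,
)
from .spatial import SpatialWeights

try:  # pragma: no cover - numba is an optional accelerator
    from numba import njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def wrap(f):
            return f

        if args and callable(args[0]):
            return args[0]
        return wrap


# ---------------------------------------------------------------------------
# Unit partition
# ---------------------------------------------------------------------------


@dataclass
class UnitPartition:
    """Assignment of every grid cell to one of n contiguous block units.

    ``unit_id`` holds labels 1..n_units; centroids are mean member-cell
    centre coordinates in km (x east along columns, y south along rows).
    """

    unit_id: np.ndarray  # (rows, cols) int, 1-based
    n_units: int
    cell_size_km: float = 1.0
    cell_area: float = 1_000_000.0

    centroids_km: np.ndarray = field(init=False)
    areas_m2: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        rows, cols = self.unit_id.shape
        rr, cc = np.meshgrid(np.arange(rows), np.arange(cols), indexing="ij")
        x = (cc.ravel() + 0.5) * self.cell_size_km
        y = (rr.ravel() + 0.5) * self.cell_size_km
        lab = self.unit_id.ravel()
        counts = np.bincount(lab, minlength=self.n_units + 1)[1:]
        if np.any(counts == 0) or lab.min() < 1 or lab.max() > self.n_units:
            raise ConfigError("unit_id labels must cover 1..n_units with no gaps")
        cx = np.bincount(lab, weights=x, minlength=self.n_units + 1)[1:] / counts
        cy = np.bincount(lab, weights=y, minlength=self.n_units + 1)[1:] / counts
        self.centroids_km = np.column_stack([cx, cy])
        self.areas_m2 = counts.astype(float) * self.cell_area

    @property
    def counts(self) -> np.ndarray:
        return (self.areas_m2 / self.cell_area).astype(int)


def _split_sizes(total: int, parts: int) -> list:
    """Split ``total`` into ``parts`` integers differing by at most 1."""
    base, rem = divmod(total, parts)
    return [base + 1 if i < rem else base for i in range(parts)]


def partition_units(
    grid_rows: int,
    grid_cols: int,
    n_units: int,
    cell_size_km: float = 1.0,
    cell_area: float = 1_000_000.0,
) -> UnitPartition:
    """Partition the grid into near-equal-area contiguous rectangular blocks.

    Rows are cut into horizontal stripes and each stripe into column blocks;
    stripe count is chosen near sqrt(n_units) so blocks stay roughly square.
    """
    n_cells = grid_rows * grid_cols
    if n_units > n_cells:
        raise ConfigError(
            f"n_units ({n_units}) exceeds grid cells ({n_cells})"
        )
    n_stripes = max(1, min(grid_rows, round(np.sqrt(n_units))))
    # every stripe must fit its block count within grid_cols
    while max(_split_sizes(n_units, n_stripes)) > grid_cols:
        n_stripes += 1
        if n_stripes > grid_rows:
            raise ConfigError("cannot tile n_units rectangular blocks on this grid")
    per_stripe = _split_sizes(n_units, n_stripes)
    stripe_heights = _split_sizes(grid_rows, n_stripes)
    unit_id = np.zeros((grid_rows, grid_cols), dtype=np.int32)
    uid = 1
    r0 = 0
    for h, k in zip(stripe_heights, per_stripe):
        widths = _split_sizes(grid_cols, k)
        c0 = 0
        for w in widths:
            unit_id[r0 : r0 + h, c0 : c0 + w] = uid
            uid += 1
            c0 += w
        r0 += h
    return UnitPartition(
        unit_id=unit_id,
        n_units=n_units,
        cell_size_km=cell_size_km,
        cell_area=cell_area,
    )


# ---------------------------------------------------------------------------
# Region dataset
# ---------------------------------------------------------------------------


@dataclass
class RegionDataset:
    """All layers of a two-epoch synthetic region.

    Per epoch: integer land cover, integer DN in [0, 63], NPP (kg C/m2),
    a 12-layer monthly EVI stack, ET (m/yr) and a 14-layer summer LST stack
    (K). Epoch-invariant: hydrologic soil group (1..4 = A..D) and the unit
    partition.
    """

    config: RegionConfig
    land_cover: Dict[str, np.ndarray]
    dn: Dict[str, np.ndarray]
    npp: Dict[str, np.ndarray]
    evi: Dict[str, np.ndarray]  # (12, rows, cols)
    et: Dict[str, np.ndarray]
    lst: Dict[str, np.ndarray]  # (14, rows, cols)
    soil_group: np.ndarray
    partition: UnitPartition

    @property
    def epochs(self):
        return self.config.epochs

    @property
    def shape(self):
        return (self.config.grid_rows, self.config.grid_cols)


def _core_distance_km(cfg: RegionConfig) -> np.ndarray:
    rr, cc = np.meshgrid(
        np.arange(cfg.grid_rows), np.arange(cfg.grid_cols), indexing="ij"
    )
    d = np.full((cfg.grid_rows, cfg.grid_cols), np.inf)
    s = cfg.cell_size_km
    for r0, c0 in cfg.urban_core_centers:
        dk = np.hypot((rr + 0.5 - r0) * s, (cc + 0.5 - c0) * s)
        d = np.minimum(d, dk)
    return d


def _dn_clean(cfg: RegionConfig, epoch_index: int) -> np.ndarray:
    decay = cfg.dn_decay * (cfg.dn_growth if epoch_index == 1 else 1.0)
    return cfg.dn_max * np.exp(-_core_distance_km(cfg) / decay)


_SEASON = 1.0 + 0.6 * np.sin(2.0 * np.pi * (np.arange(12) + 0.5 - 3.0) / 12.0)
_DAY_EFFECT = 0.8 * np.sin(2.0 * np.pi * np.arange(14) / 14.0)


def generate_region(config: RegionConfig) -> RegionDataset:
    """Generate a seeded synthetic region dataset.

    Construction order: DN surfaces (exponential decay from the nearest
    urban core, brighter at t1), t0 artificial footprint from the noise-free
    DN threshold, remaining land cover from a smoothed distance-plus-noise
    suitability score, t1 conversion of the brightest non-artificial cells
    until ``artificial_delta`` of all cells changed, then continuous layers
    as land-cover class means plus Gaussian noise.
    """
    cfg = config
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    rows, cols = cfg.grid_rows, cfg.grid_cols
    n_cells = rows * cols
    e0, e1 = cfg.epochs

    dn_clean = {e0: _dn_clean(cfg, 0), e1: _dn_clean(cfg, 1)}
    dn = {}
    for e in (e0, e1):
        noisy = dn_clean[e] + rng.normal(0.0, cfg.noise_sd["dn"], size=(rows, cols))
        dn[e] = np.clip(np.rint(noisy), 0, 63).astype(np.int16)

    # t0 artificial surface: noise-free DN above the built-up threshold
    art0 = dn_clean[e0] > cfg.artificial_dn_threshold

    # background land cover from a suitability score: farmland near the
    # cores, grassland at mid distance, forest far out; wetland and bare
    # patches from independent smooth fields
    d = _core_distance_km(cfg)
    rough = gaussian_filter(rng.standard_normal((rows, cols)), sigma=6.0)
    rough /= max(rough.std(), 1e-12)
    score = d + 12.0 * rough
    lc0 = np.empty((rows, cols), dtype=np.int16)
    free = ~art0
    qs = np.quantile(score[free], [0.45, 0.70])
    lc0[free & (score <= qs[0])] = FARMLAND
    lc0[free & (score > qs[0]) & (score <= qs[1])] = GRASSLAND
    lc0[free & (score > qs[1])] = FOREST
    wet_field = gaussian_filter(rng.standard_normal((rows, cols)), sigma=4.0)
    wet_field /= max(wet_field.std(), 1e-12)
    bare_field = gaussian_filter(rng.standard_normal((rows, cols)), sigma=4.0)
    bare_field /= max(bare_field.std(), 1e-12)
    lc0[free & (wet_field > 1.88)] = WETLAND  # ~3% of cells
    lc0[free & (bare_field > 1.88) & (lc0 != WETLAND)] = BARE
    lc0[art0] = ARTIFICIAL

    # t1: convert the brightest non-artificial cells (peri-urban conversion)
    n_convert = int(np.rint(cfg.artificial_delta * n_cells))
    lc1 = lc0.copy()
    if n_convert > 0:
        candidates = np.flatnonzero(~art0.ravel())
        order = np.argsort(dn_clean[e1].ravel()[candidates])[::-1]
        chosen = candidates[order[:n_convert]]
        lc1.ravel()[chosen] = ARTIFICIAL
    land_cover = {e0: lc0, e1: lc1}

    # soil groups: quantiles of a smooth field -> A..D (codes 1..4)
    soil_field = gaussian_filter(rng.standard_normal((rows, cols)), sigma=8.0)
    edges = np.quantile(soil_field, [0.25, 0.5, 0.75])
    soil = np.digitize(soil_field, edges).astype(np.int16) + 1

    def class_layer(lc, means, factor=1.0, sd=0.0, lo=None, hi=None, shape2d=True):
        lut = np.zeros(max(means) + 1)
        for k, v in means.items():
            lut[k] = v
        base = lut[lc] * factor
        out = base + rng.normal(0.0, sd, size=base.shape) if sd > 0 else base.copy()
        if lo is not None or hi is not None:
            out = np.clip(out, lo, hi)
        return out

    # north-south climatic trend, independent of land cover: a fractional
    # productivity multiplier on NPP/EVI/ET and an additive LST trend
    row_norm = (np.arange(rows) + 0.5) / rows
    prod_trend = (1.0 + cfg.climate_gradient * (row_norm - 0.5))[:, None]
    lst_trend = (cfg.lst_trend * (row_norm - 0.5))[:, None]

    npp, evi, et, lst = {}, {}, {}, {}
    for idx, e in enumerate((e0, e1)):
        f = 1.0 if idx == 0 else cfg.veg_decline
        lc = land_cover[e]
        npp[e] = np.clip(
            class_layer(lc, cfg.npp_class_mean, f) * prod_trend
            + rng.normal(0.0, cfg.noise_sd["npp"], size=(rows, cols)),
            0.0,
            None,
        )
        et[e] = np.clip(
            class_layer(lc, cfg.et_class_mean, f) * prod_trend
            + rng.normal(0.0, cfg.noise_sd["et"], size=(rows, cols)),
            0.0,
            None,
        )
        evi_stack = np.empty((12, rows, cols))
        annual = class_layer(lc, cfg.evi_class_mean, f) * prod_trend
        for m in range(12):
            evi_stack[m] = np.clip(
                annual * _SEASON[m]
                + rng.normal(0.0, cfg.noise_sd["evi"], size=(rows, cols)),
                -0.2,
                1.0,
            )
        evi[e] = evi_stack
        lst_stack = np.empty((14, rows, cols))
        offset = class_layer(lc, cfg.lst_class_offset, 1.0) + lst_trend
        for j in range(14):
            lst_stack[j] = (
                cfg.lst_base
                + offset
                + _DAY_EFFECT[j]
                + rng.normal(0.0, cfg.noise_sd["lst"], size=(rows, cols))
            )
        lst[e] = lst_stack

    partition = partition_units(
        rows, cols, cfg.n_units, cell_size_km=cfg.cell_size_km, cell_area=cfg.cell_area
    )
    return RegionDataset(
        config=cfg,
        land_cover=land_cover,
        dn=dn,
        npp=npp,
        evi=evi,
        et=et,
        lst=lst,
        soil_group=soil,
        partition=partition,
    )


# ---------------------------------------------------------------------------
# Autologistic field simulation (Gibbs sampler)
# ---------------------------------------------------------------------------


@njit(cache=False)
def _gibbs_sweeps(indptr, indices, data, eta_base, gamma, y, uniforms):
    n_sweeps = uniforms.shape[0]
    n = y.shape[0]
    for s in range(n_sweeps):
        for i in range(n):
            lag = 0.0
            for p in range(indptr[i], indptr[i + 1]):
                lag += data[p] * y[indices[p]]
            eta = eta_base[i] + gamma * lag
            pr = 1.0 / (1.0 + np.exp(-eta))
            y[i] = 1.0 if uniforms[s, i] < pr else 0.0
    return y


def simulate_autologistic_field(
    weights: SpatialWeights,
    alpha: float,
    beta: Optional[np.ndarray] = None,
    covariates: Optional[np.ndarray] = None,
    gamma: float = 0.0,
    n_sweeps: int = 50,
    seed: Optional[int] = None,
    init: Optional[np.ndarray] = None,
) -> np.ndarray:
    """Draw a binary field from the autologistic model by Gibbs sampling.

    Each full sweep resamples every unit in order from its conditional
    logit: logit P(y_i=1 | rest) = alpha + x_i' beta + gamma * sum_j w_ij y_j.
    Returns the 0/1 state after ``n_sweeps`` sweeps.
    """
    n = weights.n
    if n_sweeps < 1:
        raise ValueError("n_sweeps must be >= 1")
    if covariates is None:
        eta_base = np.full(n, float(alpha))
    else:
        X = np.atleast_2d(np.asarray(covariates, dtype=float))
        if X.shape[0] != n:
            raise ValueError(
                f"covariates rows ({X.shape[0]}) do not match units ({n})"
            )
        b = np.zeros(X.shape[1]) if beta is None else np.asarray(beta, dtype=float)
        if b.shape[0] != X.shape[1]:
            raise ValueError("beta length does not match covariate columns")
        eta_base = alpha + X @ b
    rng = np.random.default_rng(seed)
    if init is None:
        y = (rng.random(n) < 0.5).astype(np.float64)
    else:
        y = np.asarray(init, dtype=np.float64).copy()
        if y.shape[0] != n:
            raise ValueError("init length does not match units")
    uniforms = rng.random((n_sweeps, n))
    y = _gibbs_sweeps(
        weights.indptr.astype(np.int64),
        weights.indices.astype(np.int64),
        weights.data.astype(np.float64),
        eta_base.astype(np.float64),
        float(gamma),
        y,
        uniforms,
    )
    return y.astype(np.int8)
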