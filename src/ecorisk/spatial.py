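"""Spatial statistics over assessing units.

Distance-band spatial weights, global and Anselin local Moran's I with the
four LISA cluster types, and the autologistic risk-probability model

    p_i = P(y_i = 1 | neighbours) = logistic(alpha + x_i' beta + gamma * L_i),

with spatial lag L_i = sum_j w_ij y_j, fitted by maximum pseudo-likelihood
(a logistic maximum-likelihood fit treating the observed lag as a
covariate).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

log = logging.getLogger(__name__)

LISA_CATEGORIES = ("high-high", "high-low", "low-high", "low-low", "not-significant")


class SpatialError(ValueError):
    pass


@dataclass
class SpatialWeights:
    """Sparse neighbour structure in CSR form.

    ``style`` is ``"binary"`` (symmetric 0/1) or ``"row"`` (row-standardised,
    rows sum to 1, or 0 for islands).
    """

    n: int
    indptr: np.ndarray
    indices: np.ndarray
    data: np.ndarray
    style: str = "binary"

    def __post_init__(self) -> None:
        if self.style not in ("binary", "row"):
            raise SpatialError(f"unknown weights style {self.style!r}")

    @classmethod
    def from_neighbor_lists(
        cls, neighbors: Sequence[Sequence[int]], style: str = "binary"
    ) -> "SpatialWeights":
        n = len(neighbors)
        indptr = np.zeros(n + 1, dtype=np.int64)
        idx = []
        for i, nb in enumerate(neighbors):
            nb = sorted(nb)
            if i in nb:
                raise SpatialError(f"unit {i} listed as its own neighbour")
            idx.extend(nb)
            indptr[i + 1] = indptr[i] + len(nb)
        indices = np.asarray(idx, dtype=np.int64)
        data = np.ones(len(indices), dtype=float)
        w = cls(n=n, indptr=indptr, indices=indices, data=data, style="binary")
        return w.row_standardized() if style == "row" else w

    @classmethod
    def distance_band(
        cls,
        centroids_km: np.ndarray,
        band_km: float = 40.0,
        style: str = "binary",
    ) -> "SpatialWeights":
        """Neighbours are pairs with 0 < distance <= ``band_km``.

        Units with no neighbour inside the band are retained as islands with
        an empty row; a warning reports how many.
        """
        pts = np.asarray(centroids_km, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 2:
            raise SpatialError("centroids must be an (n, 2) array of km coordinates")
        n = len(pts)
        if n < 2:
            raise SpatialError("need at least 2 units to build weights")
        d = squareform(pdist(pts))
        off_diag = d[~np.eye(n, dtype=bool)]
        if off_diag.size and off_diag.min() == 0.0:
            raise SpatialError("duplicate centroids: zero distance between units")
        adj = (d > 0) & (d <= band_km)
        neighbors = [np.flatnonzero(adj[i]).tolist() for i in range(n)]
        islands = sum(1 for nb in neighbors if not nb)
        if islands:
            warnings.warn(
                f"{islands} island unit(s) with no neighbour within {band_km} km",
                stacklevel=2,
            )
        return cls.from_neighbor_lists(neighbors, style=style)

    @classmethod
    def lattice_rook(
        cls, nrows: int, ncols: int, style: str = "binary"
    ) -> "SpatialWeights":
        """Rook contiguity on an nrows x ncols lattice (row-major unit order)."""
        neighbors = []
        for r in range(nrows):
            for c in range(ncols):
                nb = []
                if r > 0:
                    nb.append((r - 1) * ncols + c)
                if r < nrows - 1:
                    nb.append((r + 1) * ncols + c)
                if c > 0:
                    nb.append(r * ncols + c - 1)
                if c < ncols - 1:
                    nb.append(r * ncols + c + 1)
                neighbors.append(nb)
        return cls.from_neighbor_lists(neighbors, style=style)

    # -- structure ---------------------------------------------------------

    def neighbors(self, i: int) -> np.ndarray:
        return self.indices[self.indptr[i] : self.indptr[i + 1]]

    def weights_of(self, i: int) -> np.ndarray:
        return self.data[self.indptr[i] : self.indptr[i + 1]]

    @property
    def n_links(self) -> int:
        return int(len(self.indices))

    @property
    def s0(self) -> float:
        return float(self.data.sum())

    def cardinalities(self) -> np.ndarray:
        return np.diff(self.indptr)

    def dense(self) -> np.ndarray:
        m = np.zeros((self.n, self.n))
        for i in range(self.n):
            m[i, self.neighbors(i)] = self.weights_of(i)
        return m

    def lag(self, y: np.ndarray) -> np.ndarray:
        """Spatial lag L_i = sum_j w_ij y_j."""
        y = np.asarray(y, dtype=float)
        if y.shape[0] != self.n:
            raise SpatialError(f"lag input length {y.shape[0]} != n units {self.n}")
        out = np.empty(self.n)
        for i in range(self.n):
            lo, hi = self.indptr[i], self.indptr[i + 1]
            out[i] = self.data[lo:hi] @ y[self.indices[lo:hi]]
        return out

    def row_standardized(self) -> "SpatialWeights":
        data = self.data.copy().astype(float)
        for i in range(self.n):
            lo, hi = self.indptr[i], self.indptr[i + 1]
            s = data[lo:hi].sum()
            if s > 0:
                data[lo:hi] /= s
        return SpatialWeights(
            n=self.n,
            indptr=self.indptr.copy(),
            indices=self.indices.copy(),
            data=data,
            style="row",
        )

    def assert_valid(self) -> None:
        """Symmetry in binary form; unit (or zero) row sums in row form."""
        if np.any(self.indices == np.repeat(np.arange(self.n), self.cardinalities())):
            raise SpatialError("self-neighbour found")
        if self.style == "binary":
            m = self.dense()
            if not np.array_equal(m, m.T):
                raise SpatialError("binary weights are not symmetric")
        else:
            sums = np.array(
                [self.weights_of(i).sum() for i in range(self.n)]
            )
            bad = ~(np.isclose(sums, 1.0) | (sums == 0.0))
            if bad.any():
                raise SpatialError("row-standardised rows do not sum to 1 (or 0)")

    def to_frame(self) -> pd.DataFrame:
        rows = np.repeat(np.arange(self.n), self.cardinalities())
        return pd.DataFrame({"i": rows, "j": self.indices, "w": self.data})


def distance_band_weights(
    centroids_km: np.ndarray, band_km: float = 40.0, style: str = "binary"
) -> SpatialWeights:
    """Functional alias for :meth:`SpatialWeights.distance_band`."""
    w = SpatialWeights.distance_band(centroids_km, band_km=band_km, style=style)
    w.assert_valid()
    return w


# ---------------------------------------------------------------------------
# Moran statistics
# ---------------------------------------------------------------------------


def global_morans_i(values: np.ndarray, weights: SpatialWeights) -> float:
    """Global Moran's I = (n / S0) * (z' W z) / (z' z), z = x - mean."""
    x = np.asarray(values, dtype=float)
    if x.shape[0] != weights.n:
        raise SpatialError("values length does not match weights")
    z = x - x.mean()
    denom = float(z @ z)
    if denom == 0.0:
        raise SpatialError("zero variance: Moran's I undefined")
    num = float(z @ weights.lag(z))
    return weights.n / weights.s0 * num / denom


@dataclass
class LisaResult:
    """Per-unit local Moran's I with permutation pseudo p-values."""

    local_i: np.ndarray
    p_value: np.ndarray
    category: np.ndarray  # strings from LISA_CATEGORIES
    quadrant: np.ndarray  # 1 HH, 2 LH, 3 LL, 4 HL (ignoring significance)
    alpha: float
    n_permutations: int

    def counts(self) -> Dict[str, int]:
        return {c: int((self.category == c).sum()) for c in LISA_CATEGORIES}

    def to_frame(self, unit_ids: Optional[np.ndarray] = None) -> pd.DataFrame:
        n = len(self.local_i)
        ids = np.arange(1, n + 1) if unit_ids is None else unit_ids
        return pd.DataFrame(
            {
                "unit_id": ids,
                "local_I": self.local_i,
                "p_value": self.p_value,
                "category": self.category,
            }
        )


def local_morans_i(
    values: np.ndarray,
    weights: SpatialWeights,
    n_permutations: int = 999,
    alpha: float = 0.05,
    seed: Optional[int] = None,
) -> LisaResult:
    """Anselin local Moran's I with conditional permutation inference.

    I_i = z_i * sum_j w_ij z_j where z is standardised by the population
    standard deviation, so that with row-standardised weights the mean of
    the local statistics equals global Moran's I. Pseudo p-values are
    one-sided on |I_i| (two-sided equivalent); significant units are
    classified high-high / high-low / low-high / low-low by the signs of
    their own value and their neighbourhood lag.
    """
    x = np.asarray(values, dtype=float)
    n = weights.n
    if x.shape[0] != n:
        raise SpatialError("values length does not match weights")
    if n_permutations < 99:
        raise SpatialError("n_permutations must be >= 99")
    sd = x.std()  # population sd
    if sd == 0.0:
        raise SpatialError("zero variance: local Moran's I undefined")
    z = (x - x.mean()) / sd
    lag = weights.lag(z)
    local_i = z * lag

    rng = np.random.default_rng(seed)
    p = np.empty(n)
    # conditional permutation: hold z_i fixed, draw its neighbours from the
    # remaining n-1 values without replacement
    others = np.arange(n - 1)
    for i in range(n):
        k = int(weights.indptr[i + 1] - weights.indptr[i])
        if k == 0:
            p[i] = 1.0
            continue
        pool = np.delete(z, i)
        keys = rng.random((n_permutations, n - 1))
        draw = np.argpartition(keys, k - 1, axis=1)[:, :k]
        wdat = weights.weights_of(i)
        sim = pool[draw] @ wdat
        sim_i = z[i] * sim
        p[i] = (np.count_nonzero(np.abs(sim_i) >= abs(local_i[i])) + 1) / (
            n_permutations + 1
        )
    del others

    quadrant = np.where(
        z > 0, np.where(lag > 0, 1, 4), np.where(lag > 0, 2, 3)
    )
    category = np.full(n, "not-significant", dtype=object)
    sig = p <= alpha
    names = {1: "high-high", 2: "low-high", 3: "low-low", 4: "high-low"}
    for q, name in names.items():
        category[sig & (quadrant == q)] = name
    return LisaResult(
        local_i=local_i,
        p_value=p,
        category=category.astype(str),
        quadrant=quadrant,
        alpha=alpha,
        n_permutations=n_permutations,
    )


# ---------------------------------------------------------------------------
# Autologistic model
# ---------------------------------------------------------------------------


def binarize_risk(levels: np.ndarray, cutoff: int = 4) -> np.ndarray:
    """Map ordinal risk levels to a binary outcome: 1 iff level >= cutoff.

    With the default cutoff IV, high probability corresponds to levels IV-V.
    """
    lv = np.asarray(levels, dtype=int)
    if np.any((lv < 1) | (lv > 5)):
        raise SpatialError("risk levels must lie in 1..5")
    return (lv >= cutoff).astype(int)


@dataclass
class AutologisticFit:
    """MPLE fit of the autologistic model; reports pseudo-R2 and AIC.

    AIC is computed from the pseudo-likelihood (-2 logPL + 2p). The
    pseudo-likelihood is not a true likelihood under spatial dependence, so
    this AIC is a relative diagnostic only.
    """

    params: np.ndarray  # (intercept, betas..., gamma?) on the fitted design
    term_names: tuple
    alpha: float
    beta: np.ndarray
    gamma: Optional[float]
    loglik: float
    pseudo_r2: float
    aic: float
    converged: bool
    n_iter: int
    has_lag: bool = True
    message: str = ""
    fitted_prob: np.ndarray = field(default=None, repr=False)

    def to_frame(self) -> pd.DataFrame:
        rows = list(zip(self.term_names, self.params))
        rows.append(("pseudo_R2", self.pseudo_r2))
        rows.append(("AIC", self.aic))
        return pd.DataFrame(rows, columns=["term", "estimate"])


def _newton_logistic(
    X: np.ndarray, y: np.ndarray, tol: float = 1e-8, max_iter: int = 100
):
    """Plain Newton-Raphson for logistic maximum likelihood.

    Returns (params, loglik, converged, n_iter, message). A vanishing-
    curvature direction (quasi-separation) is stabilised with a tiny ridge
    and flagged through the message.
    """
    n, p = X.shape
    beta = np.zeros(p)
    message = ""
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        # under separation eta diverges before the loop bails out; the
        # saturated probabilities are exact, so the overflow is harmless
        eta = np.clip(X @ beta, -500.0, 500.0)
        mu = 1.0 / (1.0 + np.exp(-eta))
        grad = X.T @ (y - mu)
        w = mu * (1.0 - mu)
        H = (X * w[:, None]).T @ X
        try:
            step = np.linalg.solve(H + 1e-12 * np.eye(p), grad)
        except np.linalg.LinAlgError:
            message = "singular Hessian"
            break
        # step halving to keep the log-likelihood non-decreasing
        ll_old = float(y @ eta - np.logaddexp(0.0, eta).sum())
        scale = 1.0
        for _ in range(30):
            cand = beta + scale * step
            eta_c = X @ cand
            ll_new = float(y @ eta_c - np.logaddexp(0.0, eta_c).sum())
            if ll_new >= ll_old - 1e-12:
                break
            scale *= 0.5
        beta = beta + scale * step
        if np.max(np.abs(grad)) < tol or np.max(np.abs(scale * step)) < tol:
            converged = True
            break
    eta = X @ beta
    ll = float(y @ eta - np.logaddexp(0.0, eta).sum())
    if np.max(np.abs(beta)) > 50:
        converged = False
        message = message or "coefficients diverging: possible perfect separation"
    return beta, ll, converged, it, message


def _ridge_logistic(
    X: np.ndarray, y: np.ndarray, lam: float, tol: float = 1e-9, max_iter: int = 500
) -> np.ndarray:
    """Weakly L2-penalised logistic fit (intercept unpenalised).

    Used only as a stabilising fallback when the pseudo-likelihood is
    unbounded (perfect or quasi-perfect separation): the penalised optimum
    is finite and its direction approximates the maximum-margin separator.
    """
    n, p = X.shape
    pen = np.ones(p)
    pen[0] = 0.0
    beta = np.zeros(p)

    def pll(b):
        eta = np.clip(X @ b, -500, 500)
        return float(y @ eta - np.logaddexp(0.0, eta).sum() - lam / 2 * (pen * b * b).sum())

    for _ in range(max_iter):
        eta = np.clip(X @ beta, -500, 500)
        mu = 1.0 / (1.0 + np.exp(-eta))
        grad = X.T @ (y - mu) - lam * pen * beta
        w = mu * (1.0 - mu)
        H = (X * w[:, None]).T @ X + lam * np.diag(pen) + 1e-10 * np.eye(p)
        step = np.linalg.solve(H, grad)
        base = pll(beta)
        scale = 1.0
        for _ in range(40):
            if pll(beta + scale * step) >= base - 1e-12:
                break
            scale *= 0.5
        beta = beta + scale * step
        if np.max(np.abs(scale * step)) < tol:
            break
    return beta


def autologistic_mple(
    y: np.ndarray,
    X: np.ndarray,
    weights: Optional[SpatialWeights],
    term_names: Optional[Sequence[str]] = None,
    tol: float = 1e-8,
    max_iter: int = 100,
    separation_ridge: float = 1e-2,
) -> AutologisticFit:
    """Maximum pseudo-likelihood fit of the autologistic model.

    The spatial lag of the observed outcome, L_i = sum_j w_ij y_j, enters the
    design as an ordinary covariate; the pseudo-likelihood is then the
    product of the full conditionals and maximising it reduces to a logistic
    ML fit by Newton iterations. If ``weights`` is None or has no links, the
    lag column is dropped and the fit is an ordinary logistic regression.

    Under perfect (or quasi-perfect) separation the pseudo-likelihood has no
    maximiser; the fit is flagged non-converged and the reported
    coefficients come from a weakly ridge-penalised refit
    (``separation_ridge``, intercept unpenalised) whose finite optimum
    tracks the maximum-margin direction.
    """
    y = np.asarray(y, dtype=float)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] != y.shape[0]:
        raise SpatialError("X rows do not match y length")
    if y.min() == y.max():
        raise SpatialError("outcome is constant: cannot fit")
    n, k = X.shape
    has_lag = weights is not None and weights.n_links > 0
    cols = [np.ones(n), *(X[:, j] for j in range(k))]
    if term_names is None:
        term_names = [f"x{j + 1}" for j in range(k)]
    names = ["interception", *term_names]
    if has_lag:
        cols.append(weights.lag(y))
        names.append("spatial_lag")
    D = np.column_stack(cols)
    params, ll, converged, n_iter, message = _newton_logistic(
        D, y, tol=tol, max_iter=max_iter
    )
    if not converged:
        params = _ridge_logistic(D, y, lam=separation_ridge)
        eta_pen = np.clip(D @ params, -500, 500)
        ll = float(y @ eta_pen - np.logaddexp(0.0, eta_pen).sum())
        message = (message or "max iterations") + "; ridge-stabilised coefficients"
        warnings.warn(
            f"autologistic MPLE did not fully converge: {message}",
            stacklevel=2,
        )
    # null model for McFadden pseudo-R2
    p0 = y.mean()
    ll0 = float(n * (p0 * np.log(p0) + (1 - p0) * np.log(1 - p0)))
    pseudo_r2 = 1.0 - ll / ll0 if ll0 != 0 else np.nan
    n_par = D.shape[1]
    aic = -2.0 * ll + 2.0 * n_par
    gamma = float(params[-1]) if has_lag else None
    beta = params[1 : 1 + k]
    eta = D @ params
    return AutologisticFit(
        params=params,
        term_names=tuple(names),
        alpha=float(params[0]),
        beta=beta,
        gamma=gamma,
        loglik=ll,
        pseudo_r2=float(pseudo_r2),
        aic=float(aic),
        converged=converged,
        n_iter=n_iter,
        has_lag=has_lag,
        message=message,
        fitted_prob=1.0 / (1.0 + np.exp(-np.clip(eta, -500.0, 500.0))),
    )
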