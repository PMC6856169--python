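"""Risk-level discovery and prediction.

Five risk levels are discovered on the first-epoch PSR triples with
K-Means (Lloyd iterations, k-means++ seeding, best of several restarts),
ordered I..V by the centroid risk score s = pressure - status - response
(level V = highest risk: high pressure with low status and response), and a
Gaussian-kernel radial-basis-function network trained on the first epoch
carries the levels to the second epoch.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, Optional, Tuple

import numpy as np

ROMAN = {1: "I", 2: "II", 3: "III", 4: "IV", 5: "V"}


class RiskError(ValueError):
    pass


# ---------------------------------------------------------------------------
# K-Means
# ---------------------------------------------------------------------------


def _kmeans_pp_init(X: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    n = X.shape[0]
    centers = np.empty((k, X.shape[1]))
    centers[0] = X[rng.integers(n)]
    d2 = ((X - centers[0]) ** 2).sum(axis=1)
    for j in range(1, k):
        total = d2.sum()
        if total == 0:
            centers[j] = X[rng.integers(n)]
        else:
            centers[j] = X[rng.choice(n, p=d2 / total)]
        d2 = np.minimum(d2, ((X - centers[j]) ** 2).sum(axis=1))
    return centers


def _lloyd(
    X: np.ndarray, centers: np.ndarray, n_iter: int
) -> Tuple[np.ndarray, np.ndarray, float]:
    k = centers.shape[0]
    prev_wcss = np.inf
    labels = None
    for _ in range(n_iter):
        d2 = ((X[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
        labels = d2.argmin(axis=1)
        wcss = float(d2[np.arange(len(X)), labels].sum())
        # Lloyd monotonicity: assignment+update never increases WCSS
        assert wcss <= prev_wcss + 1e-9, "WCSS increased across a Lloyd iteration"
        if wcss == prev_wcss:
            break
        prev_wcss = wcss
        new_centers = centers.copy()
        for j in range(k):
            members = X[labels == j]
            if len(members):
                new_centers[j] = members.mean(axis=0)
            else:
                # reseed an empty cluster to the point farthest from its centre
                far = d2[np.arange(len(X)), labels].argmax()
                new_centers[j] = X[far]
        centers = new_centers
    d2 = ((X[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
    labels = d2.argmin(axis=1)
    wcss = float(d2[np.arange(len(X)), labels].sum())
    return labels, centers, wcss


def kmeans(
    points: np.ndarray,
    k: int = 5,
    n_iter: int = 100,
    n_restarts: int = 10,
    seed: Optional[int] = None,
) -> Tuple[np.ndarray, np.ndarray, float]:
    """Seeded K-Means; returns (labels, centroids, wcss) of the best restart."""
    X = np.atleast_2d(np.asarray(points, dtype=float))
    n = X.shape[0]
    if n < k:
        raise RiskError(f"need at least k={k} points, got {n}")
    rng = np.random.default_rng(seed)
    best = None
    for _ in range(max(1, n_restarts)):
        centers0 = _kmeans_pp_init(X, k, rng)
        labels, centers, wcss = _lloyd(X, centers0, n_iter)
        if best is None or wcss < best[2] - 1e-15:
            best = (labels, centers, wcss)
    return best


def rank_risk_levels(centroids: np.ndarray) -> Dict[int, int]:
    """Map cluster index -> ordinal risk level (1=I lowest .. k=V highest).

    Centroid columns are (pressure, status, response); risk score
    s = pressure - status - response. The highest score gets the highest
    level; ties break by higher pressure, then lower status.
    """
    C = np.atleast_2d(np.asarray(centroids, dtype=float))
    k = C.shape[0]
    s = C[:, 0] - C[:, 1] - C[:, 2]
    order = sorted(range(k), key=lambda j: (s[j], C[j, 0], -C[j, 1]))
    return {cluster: rank + 1 for rank, cluster in enumerate(order)}


def risk_shares(levels: np.ndarray, k: int = 5) -> Dict[int, float]:
    """Percentage of units per level 1..k; absent levels reported as 0."""
    lv = np.asarray(levels, dtype=int)
    if lv.size == 0:
        raise RiskError("empty level vector")
    counts = np.bincount(lv, minlength=k + 1)[1:]
    return {lvl + 1: float(c) / lv.size * 100.0 for lvl, c in enumerate(counts)}


# ---------------------------------------------------------------------------
# RBF network
# ---------------------------------------------------------------------------


@dataclass
class RBFNet:
    """Gaussian-kernel RBF classifier with ridge-regularised output weights."""

    centers: np.ndarray
    sigma: float
    weights: np.ndarray  # (n_centers, n_classes)
    classes: np.ndarray  # ordinal levels in output-column order
    train_accuracy: float = np.nan
    test_accuracy: float = np.nan

    def activations(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        d2 = ((X[:, None, :] - self.centers[None, :, :]) ** 2).sum(axis=2)
        return np.exp(-d2 / (2.0 * self.sigma**2))

    def predict(self, X: np.ndarray) -> np.ndarray:
        if self.weights is None:
            raise RiskError("RBF network is not trained")
        scores = self.activations(X) @ self.weights
        return self.classes[scores.argmax(axis=1)]


@dataclass
class RiskModel:
    """Clustering + level map + RBF classifier for one assessment."""

    centroids: np.ndarray
    level_map: Dict[int, int]
    net: RBFNet
    wcss: float
    train_accuracy: float
    test_accuracy: float

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.net.predict(X)


def _fit_output_weights(
    X: np.ndarray, levels: np.ndarray, centers: np.ndarray, sigma: float,
    ridge: float, classes: np.ndarray
) -> np.ndarray:
    d2 = ((X[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
    phi = np.exp(-d2 / (2.0 * sigma**2))
    T = (levels[:, None] == classes[None, :]).astype(float)
    M = centers.shape[0]
    A = phi.T @ phi + ridge * np.eye(M)
    return np.linalg.solve(A, phi.T @ T)


def rbf_train(
    X: np.ndarray,
    levels: np.ndarray,
    n_neurons: int = 160,
    ridge: float = 1e-8,
    seed: Optional[int] = None,
    test_fraction: float = 0.2,
) -> RBFNet:
    """Train a Gaussian-kernel RBF network on ordinal level targets.

    Centers are K-Means centroids over X with M = min(n_neurons, n)
    centers; kernel width sigma = d_max / sqrt(2 M) with d_max the maximum
    inter-center distance; output weights solve ridge-regularised least
    squares against one-hot targets; prediction is the argmax output.
    Accuracy is reported on a seeded 80/20 split, then the network is refit
    on all data.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    levels = np.asarray(levels, dtype=int)
    n = X.shape[0]
    if n != levels.shape[0]:
        raise RiskError("X rows do not match level targets")
    classes = np.unique(levels)
    rng = np.random.default_rng(seed)

    # seeded split; singleton levels are forced into training
    counts = {c: int((levels == c).sum()) for c in classes}
    singles = [c for c, m in counts.items() if m < 2]
    if singles:
        warnings.warn(
            f"level(s) {singles} have a single member; forced into training",
            stacklevel=2,
        )
    perm = rng.permutation(n)
    n_test = int(round(test_fraction * n))
    test_idx = [i for i in perm[:n_test] if counts[levels[i]] >= 2]
    # keep at least one member of every level in training
    test_set = set(test_idx)
    for c in classes:
        members = np.flatnonzero(levels == c)
        if all(i in test_set for i in members):
            test_set.discard(members[0])
    test_idx = np.array(sorted(test_set), dtype=int)
    train_idx = np.setdiff1d(np.arange(n), test_idx)

    def build(idx: np.ndarray) -> RBFNet:
        Xi, yi = X[idx], levels[idx]
        M = min(n_neurons, len(idx))
        if M == len(idx) and len(np.unique(Xi, axis=0)) == len(idx):
            centers = Xi.copy()
        else:
            _, centers, _ = kmeans(
                Xi, k=M, n_iter=100, n_restarts=3,
                seed=int(rng.integers(2**31 - 1)),
            )
        dmax = 0.0
        if M > 1:
            diff = ((centers[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
            dmax = float(np.sqrt(diff.max()))
        sigma = dmax / np.sqrt(2.0 * M) if dmax > 0 else 1.0
        w = _fit_output_weights(Xi, yi, centers, sigma, ridge, classes)
        return RBFNet(centers=centers, sigma=sigma, weights=w, classes=classes)

    net_split = build(train_idx)
    train_acc = float((net_split.predict(X[train_idx]) == levels[train_idx]).mean())
    if len(test_idx):
        test_acc = float((net_split.predict(X[test_idx]) == levels[test_idx]).mean())
    else:
        test_acc = np.nan
    net = build(np.arange(n))
    net.train_accuracy = train_acc
    net.test_accuracy = test_acc
    return net


def rbf_predict(net: RBFNet, X: np.ndarray) -> np.ndarray:
    """Predict ordinal risk levels for new PSR triples."""
    return net.predict(X)


def fit_risk_model(
    psr_t0: np.ndarray,
    k: int = 5,
    n_iter: int = 100,
    n_restarts: int = 10,
    n_neurons: int = 160,
    ridge: float = 1e-8,
    seed: Optional[int] = None,
) -> Tuple[RiskModel, np.ndarray]:
    """Cluster first-epoch PSR triples, rank levels, train the RBF net.

    Returns the model and the first-epoch level vector.
    """
    labels, centroids, wcss = kmeans(
        psr_t0, k=k, n_iter=n_iter, n_restarts=n_restarts, seed=seed
    )
    level_map = rank_risk_levels(centroids)
    levels_t0 = np.array([level_map[c] for c in labels], dtype=int)
    net = rbf_train(psr_t0, levels_t0, n_neurons=n_neurons, ridge=ridge, seed=seed)
    model = RiskModel(
        centroids=centroids,
        level_map=level_map,
        net=net,
        wcss=wcss,
        train_accuracy=net.train_accuracy,
        test_accuracy=net.test_accuracy,
    )
    return model, levels_t0
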