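"""Independent reference implementations used only to check the package."""

import itertools

import numpy as np


def exhaustive_kmeans_wcss(X: np.ndarray, k: int) -> float:
    """Minimum WCSS over every assignment of n points to at most k clusters."""
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    best = np.inf
    for assign in itertools.product(range(k), repeat=n):
        a = np.asarray(assign)
        wcss = 0.0
        for j in range(k):
            members = X[a == j]
            if len(members):
                c = members.mean(axis=0)
                wcss += float(((members - c) ** 2).sum())
        best = min(best, wcss)
    return best


def brute_local_moran(values: np.ndarray, w_dense: np.ndarray) -> np.ndarray:
    """Double-loop Anselin local I with population-sd standardised values."""
    x = np.asarray(values, dtype=float)
    n = len(x)
    z = (x - x.mean()) / x.std()
    out = np.zeros(n)
    for i in range(n):
        s = 0.0
        for j in range(n):
            s += w_dense[i, j] * z[j]
        out[i] = z[i] * s
    return out


def irls_logistic(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Logistic ML via statsmodels GLM (IRLS); X includes the intercept column."""
    import statsmodels.api as sm

    model = sm.GLM(y, X, family=sm.families.Binomial())
    return np.asarray(model.fit().params, dtype=float)
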