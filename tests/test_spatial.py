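"""Spatial weights, Moran statistics and the autologistic MPLE."""

import numpy as np
import pytest

from oracles import brute_local_moran, irls_logistic
from ecorisk.spatial import (
    AutologisticFit,
    SpatialError,
    SpatialWeights,
    autologistic_mple,
    binarize_risk,
    distance_band_weights,
    global_morans_i,
    local_morans_i,
)
from ecorisk.synthetic import simulate_autologistic_field


# ---------------------------------------------------------------------------
# weights
# ---------------------------------------------------------------------------


def test_band_inclusion_and_exclusion():
    w39 = SpatialWeights.distance_band(np.array([[0.0, 0.0], [39.0, 0.0]]))
    assert list(w39.neighbors(0)) == [1]
    with pytest.warns(UserWarning, match="island"):
        w41 = SpatialWeights.distance_band(np.array([[0.0, 0.0], [41.0, 0.0]]))
    assert list(w41.neighbors(0)) == []


def test_band_boundary_is_inclusive():
    w = SpatialWeights.distance_band(np.array([[0.0, 0.0], [40.0, 0.0]]))
    assert list(w.neighbors(0)) == [1]


def test_row_standardised_four_neighbors_quarter():
    pts = np.array([[0.0, 0.0], [10.0, 0.0], [-10.0, 0.0], [0.0, 10.0], [0.0, -10.0]])
    w = SpatialWeights.distance_band(pts, band_km=15.0, style="row")
    assert np.allclose(w.weights_of(0), 0.25)
    w.assert_valid()


def test_duplicate_centroids_error():
    with pytest.raises(SpatialError, match="duplicate"):
        SpatialWeights.distance_band(np.array([[1.0, 1.0], [1.0, 1.0]]))


def test_islands_warn_and_keep_empty_rows():
    pts = np.array([[0.0, 0.0], [10.0, 0.0], [500.0, 500.0]])
    with pytest.warns(UserWarning, match="island"):
        w = SpatialWeights.distance_band(pts, band_km=40.0)
    assert list(w.neighbors(2)) == []
    w.assert_valid()
    wr = w.row_standardized()
    wr.assert_valid()
    assert wr.weights_of(2).size == 0


def test_self_neighbour_rejected():
    with pytest.raises(SpatialError, match="own neighbour"):
        SpatialWeights.from_neighbor_lists([[0], []])


def test_binary_symmetry_validated():
    w = distance_band_weights(np.random.default_rng(0).uniform(0, 100, (20, 2)))
    m = w.dense()
    assert np.array_equal(m, m.T)


def test_lattice_rook_cardinalities_and_lag():
    w = SpatialWeights.lattice_rook(3, 3)
    card = w.cardinalities()
    assert card[0] == 2 and card[4] == 4 and card[1] == 3
    y = np.arange(9.0)
    # centre cell 4 has neighbours 1, 3, 5, 7
    assert w.lag(y)[4] == 1 + 3 + 5 + 7
    with pytest.raises(SpatialError, match="length"):
        w.lag(np.ones(5))


# ---------------------------------------------------------------------------
# Moran statistics
# ---------------------------------------------------------------------------


def test_global_moran_checkerboard_negative():
    w = SpatialWeights.lattice_rook(4, 4)
    rr, cc = np.meshgrid(range(4), range(4), indexing="ij")
    checker = ((rr + cc) % 2).astype(float).ravel()
    assert global_morans_i(checker, w) < 0


def test_global_moran_segregated_positive():
    w = SpatialWeights.lattice_rook(4, 4)
    blocks = np.zeros((4, 4))
    blocks[:2] = 1.0
    assert global_morans_i(blocks.ravel(), w) > 0


def test_global_moran_constant_errors():
    w = SpatialWeights.lattice_rook(3, 3)
    with pytest.raises(SpatialError, match="variance"):
        global_morans_i(np.ones(9), w)


def test_anselin_identity_mean_local_equals_global():
    rng = np.random.default_rng(13)
    w = SpatialWeights.lattice_rook(6, 6, style="row")
    x = rng.normal(size=36)
    lisa = local_morans_i(x, w, n_permutations=99, seed=0)
    assert lisa.local_i.mean() == pytest.approx(global_morans_i(x, w), abs=1e-12)


def test_local_moran_brute_force_oracle():
    rng = np.random.default_rng(14)
    pts = rng.uniform(0, 120, (30, 2))
    w = SpatialWeights.distance_band(pts, band_km=40.0)
    x = rng.normal(size=30)
    lisa = local_morans_i(x, w, n_permutations=99, seed=1)
    assert np.max(np.abs(lisa.local_i - brute_local_moran(x, w.dense()))) < 1e-12


def test_local_moran_high_low_detection():
    rng = np.random.default_rng(15)
    w = SpatialWeights.lattice_rook(5, 5)
    # mixed field so the permutation pool is heterogeneous; the centre is a
    # high spike whose four neighbours are all at the low extreme
    x = rng.normal(5.0, 0.1, 25)
    x[[0, 2, 4, 10, 14, 20, 22, 24]] = rng.normal(0.0, 0.1, 8)
    x[12] = 10.0
    x[[7, 11, 13, 17]] = -5.0 + rng.normal(0.0, 0.1, 4)
    lisa = local_morans_i(x, w, n_permutations=999, alpha=0.05, seed=2)
    assert lisa.category[12] == "high-low"
    assert lisa.p_value[12] <= 0.05


def test_local_moran_errors():
    w = SpatialWeights.lattice_rook(3, 3)
    with pytest.raises(SpatialError, match="variance"):
        local_morans_i(np.ones(9), w, n_permutations=99)
    with pytest.raises(SpatialError, match="99"):
        local_morans_i(np.arange(9.0), w, n_permutations=50)


def test_local_moran_seeded_determinism():
    rng = np.random.default_rng(16)
    w = SpatialWeights.lattice_rook(5, 5)
    x = rng.normal(size=25)
    a = local_morans_i(x, w, n_permutations=199, seed=7)
    b = local_morans_i(x, w, n_permutations=199, seed=7)
    assert np.array_equal(a.p_value, b.p_value)
    assert np.array_equal(a.category, b.category)


# ---------------------------------------------------------------------------
# binarize_risk
# ---------------------------------------------------------------------------


def test_binarize_examples():
    assert binarize_risk(np.array([5]))[0] == 1
    assert binarize_risk(np.array([1]))[0] == 0
    out = binarize_risk(np.array([1, 2, 3, 4, 5]), cutoff=5)
    assert list(out) == [0, 0, 0, 0, 1]
    with pytest.raises(SpatialError, match="1..5"):
        binarize_risk(np.array([0, 6]))


# ---------------------------------------------------------------------------
# autologistic MPLE
# ---------------------------------------------------------------------------


def logistic_data(n=300, seed=0, beta=(0.5, 1.2, -0.8)):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, 2))
    eta = beta[0] + X @ np.array(beta[1:])
    y = (rng.random(n) < 1.0 / (1.0 + np.exp(-eta))).astype(float)
    return X, y


def test_mple_no_links_equals_plain_logistic_oracle():
    X, y = logistic_data()
    empty = SpatialWeights.from_neighbor_lists([[] for _ in range(len(y))])
    fit = autologistic_mple(y, X, empty)
    assert not fit.has_lag
    assert fit.gamma is None
    oracle = irls_logistic(np.column_stack([np.ones(len(y)), X]), y)
    assert np.max(np.abs(fit.params - oracle)) < 1e-6


def test_mple_none_weights_equals_plain_logistic_oracle():
    X, y = logistic_data(seed=3)
    fit = autologistic_mple(y, X, None)
    oracle = irls_logistic(np.column_stack([np.ones(len(y)), X]), y)
    assert np.max(np.abs(fit.params - oracle)) < 1e-6
    assert fit.converged


def test_mple_lag_design_matches_irls_oracle():
    # gamma=0 simulated field: the MPLE design including the observed lag
    # is still a plain logistic problem the IRLS oracle can solve
    w = SpatialWeights.lattice_rook(12, 12, style="row")
    y = simulate_autologistic_field(w, alpha=-0.3, gamma=0.0, n_sweeps=40,
                                    seed=21).astype(float)
    rng = np.random.default_rng(22)
    X = rng.normal(size=(144, 1))
    fit = autologistic_mple(y, X, w)
    D = np.column_stack([np.ones(144), X, w.lag(y)])
    oracle = irls_logistic(D, y)
    assert np.max(np.abs(fit.params - oracle)) < 1e-6


def test_mple_reporting_fields():
    X, y = logistic_data(seed=5)
    fit = autologistic_mple(y, X, None, term_names=("a", "b"))
    assert fit.term_names == ("interception", "a", "b")
    assert fit.aic == pytest.approx(-2 * fit.loglik + 2 * len(fit.params))
    assert 0 <= fit.pseudo_r2 <= 1
    frame = fit.to_frame()
    assert list(frame["term"]) == ["interception", "a", "b", "pseudo_R2", "AIC"]


def test_mple_separation_flagged_with_finite_ridge_coefficients():
    X = np.linspace(-1, 1, 40)[:, None]
    y = (X[:, 0] > 0).astype(float)
    with pytest.warns(UserWarning, match="converge"):
        fit = autologistic_mple(y, X, None)
    assert not fit.converged
    assert "ridge" in fit.message
    assert np.all(np.isfinite(fit.params))
    assert fit.beta[0] > 0  # direction of the separator is preserved


def test_mple_errors():
    with pytest.raises(SpatialError, match="constant"):
        autologistic_mple(np.ones(10), np.zeros((10, 1)), None)
    with pytest.raises(SpatialError, match="rows"):
        autologistic_mple(np.array([0.0, 1.0]), np.zeros((3, 1)), None)


def test_mple_recovers_positive_gamma_single_field():
    w = SpatialWeights.lattice_rook(25, 25, style="row")
    y = simulate_autologistic_field(w, alpha=-0.5, gamma=1.5, n_sweeps=80,
                                    seed=30).astype(float)
    fit = autologistic_mple(y, np.empty((len(y), 0)), w, term_names=())
    assert fit.gamma is not None and fit.gamma > 0
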