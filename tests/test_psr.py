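"""Normalisation, entropy weighting, composite assembly and correlations."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from ecorisk.psr import (
    IndicatorSpec,
    PSRError,
    assemble_psr,
    composite,
    default_specs,
    entropy_weights,
    minmax_normalize,
    pearson_matrix,
)


def specs_of(*attrs):
    return [IndicatorSpec(f"x{i}", "status", a) for i, a in enumerate(attrs)]


def hand_entropy_weights(X):
    """Straight transcription of the stated formulas, kept independent."""
    n, m = X.shape
    e = []
    for j in range(m):
        col = X[:, j]
        s = col.sum()
        p = np.full(n, 1.0 / n) if s == 0 else col / s
        acc = 0.0
        for pi in p:
            if pi > 0:
                acc += pi * np.log(pi)
        e.append(-acc / np.log(n))
    d = [1.0 - ej for ej in e]
    total = sum(d)
    if total <= 0:
        return np.full(m, 1.0 / m)
    return np.array([dj / total for dj in d])


# ---------------------------------------------------------------------------
# minmax_normalize
# ---------------------------------------------------------------------------


def test_minmax_positive_and_negative():
    out = minmax_normalize(np.array([[2.0], [4.0], [10.0]]), specs_of("positive"))
    assert np.allclose(out.ravel(), [0.0, 0.25, 1.0])
    out = minmax_normalize(np.array([[2.0], [10.0]]), specs_of("negative"))
    assert np.allclose(out.ravel(), [1.0, 0.0])


def test_minmax_constant_column_is_half_with_warning():
    with pytest.warns(UserWarning, match="constant"):
        out = minmax_normalize(np.full((3, 1), 3.0), specs_of("positive"))
    assert np.all(out == 0.5)


def test_minmax_errors():
    with pytest.raises(PSRError, match="non-finite"):
        minmax_normalize(np.array([[np.nan], [1.0]]), specs_of("positive"))
    with pytest.raises(PSRError, match="columns"):
        minmax_normalize(np.ones((3, 2)), specs_of("positive"))


@settings(max_examples=40, derandomize=True)
@given(arrays(float, (5, 3), elements=st.floats(-50, 50)))
def test_minmax_output_in_unit_interval(X):
    import warnings

    with warnings.catch_warnings():
        # hypothesis may draw constant columns; the warning path has its own test
        warnings.simplefilter("ignore", UserWarning)
        out = minmax_normalize(X, specs_of("positive", "negative", "positive"))
    assert out.min() >= 0.0 and out.max() <= 1.0


# ---------------------------------------------------------------------------
# entropy_weights
# ---------------------------------------------------------------------------


def test_entropy_constant_column_gets_zero_weight():
    X = np.column_stack([np.full(4, 0.6), np.array([0.1, 0.9, 0.3, 0.7])])
    w = entropy_weights(X)
    assert w[0] == pytest.approx(0.0, abs=1e-12)
    assert w.sum() == pytest.approx(1.0, abs=1e-12)


def test_entropy_copied_columns_split_evenly():
    col = np.array([0.2, 0.9, 0.4])
    w = entropy_weights(np.column_stack([col, col]))
    assert np.allclose(w, [0.5, 0.5])


def test_entropy_hand_oracle_3x2():
    X = np.array([[0.2, 0.8], [0.8, 0.2], [0.5, 0.5]])
    assert np.max(np.abs(entropy_weights(X) - hand_entropy_weights(X))) < 1e-10


def test_entropy_zero_column_uniform_p():
    # a zero column has uniform p, entropy 1, weight 0
    X = np.column_stack([np.zeros(4), np.array([0.1, 0.8, 0.2, 0.9])])
    w = entropy_weights(X)
    assert w[0] == pytest.approx(0.0, abs=1e-12)


def test_entropy_all_uniform_gives_equal_weights():
    w = entropy_weights(np.full((5, 3), 0.4))
    assert np.allclose(w, 1.0 / 3.0)


def test_entropy_errors():
    with pytest.raises(PSRError, match="2 rows"):
        entropy_weights(np.ones((1, 2)))
    with pytest.raises(PSRError, match=r"\[0, 1\]"):
        entropy_weights(np.array([[1.5, 0.2], [0.1, 0.3]]))


@settings(max_examples=40, derandomize=True)
@given(arrays(float, (6, 4), elements=st.floats(0, 1)))
def test_entropy_weights_nonnegative_and_sum_one(X):
    w = entropy_weights(X)
    assert np.all(w >= -1e-15)
    assert w.sum() == pytest.approx(1.0, abs=1e-9)


# ---------------------------------------------------------------------------
# composite
# ---------------------------------------------------------------------------


def test_composite_examples():
    X = np.array([[0.3, 0.9], [0.6, 0.1]])
    assert np.allclose(composite(X, np.array([1.0, 0.0])), X[:, 0])
    assert np.allclose(composite(np.ones((3, 2)), np.array([0.5, 0.5])), 1.0)


def test_composite_random_oracle():
    rng = np.random.default_rng(12)
    X = rng.uniform(size=(5, 3))
    w = rng.uniform(size=3)
    w /= w.sum()
    hand = np.array([sum(X[i, j] * w[j] for j in range(3)) for i in range(5)])
    assert np.allclose(composite(X, w), hand, atol=1e-12)


def test_composite_errors():
    with pytest.raises(PSRError, match="length"):
        composite(np.ones((2, 3)), np.array([0.5, 0.5]))
    with pytest.raises(PSRError, match="sum to 1"):
        composite(np.ones((2, 2)), np.array([0.7, 0.7]))


# ---------------------------------------------------------------------------
# assemble_psr
# ---------------------------------------------------------------------------


def toy_tables():
    """4 unit-epoch rows engineered so unit 1/t0 dominates pressure and
    unit 2/t0 sits at every status extreme (minimum for positive attributes,
    maximum for negative cn and lcr)."""
    units = [1, 2]
    rows_i = []
    rows_s = []
    rows_p = []
    for e, bump in (("t0", 0.0), ("t1", 0.1)):
        for u in units:
            hi = u == 1
            rows_i.append(
                {
                    "unit_id": u, "epoch": e,
                    "npp": (0.6 if hi else 0.1) + bump,
                    "evi": (0.5 if hi else 0.1) + bump,
                    "et": (0.4 if hi else 0.1) + bump,
                    "cn": (60.0 if hi else 90.0) - bump,
                    "carbon": (20.0 if hi else 2.0) + bump,
                    "lcr": (0.99 if hi else 1.05) - bump,
                }
            )
            rows_s.append(
                {
                    "unit_id": u, "epoch": e,
                    "provisioning_density": (1.0 if hi else 0.2) + bump,
                    "supporting_density": (1.5 if hi else 0.3) + bump,
                    "regulating_density": (2.0 if hi else 0.4) + bump,
                    "cultural_density": (0.5 if hi else 0.1) + bump,
                }
            )
            rows_p.append(
                {
                    "unit_id": u, "epoch": e,
                    "mean_dn": (60.0 if hi else 5.0) + (0.0 if e == "t0" else -1.0),
                    "artificial_ratio": (0.9 if hi else 0.0)
                    - (0.0 if e == "t0" else 0.05),
                }
            )
    return pd.DataFrame(rows_i), pd.DataFrame(rows_s), pd.DataFrame(rows_p)


def test_assemble_pressure_one_at_joint_maximum():
    ind, svc, pres = toy_tables()
    bundle = assemble_psr(ind, svc, pres)
    psr = bundle["psr"]
    row = psr[(psr["unit_id"] == 1) & (psr["epoch"] == "t0")]
    assert row["pressure"].iloc[0] == pytest.approx(1.0)


def test_assemble_status_zero_at_column_extremes():
    ind, svc, pres = toy_tables()
    psr = assemble_psr(ind, svc, pres)["psr"]
    row = psr[(psr["unit_id"] == 2) & (psr["epoch"] == "t0")]
    assert row["status"].iloc[0] == pytest.approx(0.0, abs=1e-12)


def test_assemble_composites_in_unit_interval_and_weights():
    ind, svc, pres = toy_tables()
    bundle = assemble_psr(ind, svc, pres)
    psr = bundle["psr"]
    for col in ("pressure", "status", "response"):
        assert psr[col].between(-1e-12, 1 + 1e-12).all()
    for block in ("pressure", "status", "response"):
        w = np.array(list(bundle["weights"][block].values()))
        assert w.sum() == pytest.approx(1.0)
        assert np.all(w >= 0)
    assert np.allclose(list(bundle["weights"]["pressure"].values()), 0.5)


def test_assemble_missing_indicator_named():
    ind, svc, pres = toy_tables()
    with pytest.raises(PSRError, match="cn"):
        assemble_psr(ind.drop(columns=["cn"]), svc, pres)


def test_assemble_permutation_invariance():
    ind, svc, pres = toy_tables()
    base = assemble_psr(ind, svc, pres)["psr"]
    perm = assemble_psr(
        ind.iloc[::-1].reset_index(drop=True),
        svc.sample(frac=1.0, random_state=1).reset_index(drop=True),
        pres.iloc[[2, 0, 3, 1]].reset_index(drop=True),
    )["psr"]
    merged = base.merge(perm, on=["unit_id", "epoch"], suffixes=("_a", "_b"))
    for col in ("pressure", "status", "response"):
        assert np.allclose(merged[f"{col}_a"], merged[f"{col}_b"], atol=1e-12)


def test_default_specs_block_sizes():
    specs = default_specs()
    blocks = {}
    for s in specs:
        blocks.setdefault(s.block, []).append(s)
    assert len(blocks["pressure"]) == 2
    assert len(blocks["status"]) == 6
    assert len(blocks["response"]) == 4
    negative = {s.name for s in specs if s.attribute == "negative"}
    assert negative == {"cn", "lcr"}


# ---------------------------------------------------------------------------
# pearson_matrix
# ---------------------------------------------------------------------------


def _corr_df(x, y):
    n = len(x)
    psr = pd.DataFrame(
        {"unit_id": range(1, n + 1), "epoch": "t0",
         "pressure": x, "status": x, "response": x}
    )
    ind = pd.DataFrame(
        {"unit_id": range(1, n + 1), "epoch": "t0",
         "npp": y, "evi": y, "et": y, "cn": y, "carbon": y, "lcr": y}
    )
    return pearson_matrix(psr, ind)


def test_pearson_self_is_one():
    x = [1.0, 2.0, 3.0, 5.0]
    out = _corr_df(x, x)
    assert np.allclose(out["r"], 1.0)


def test_pearson_perfect_negative():
    out = _corr_df([1.0, 2.0, 3.0], [6.0, 4.0, 2.0])
    assert np.allclose(out["r"], -1.0)


def test_pearson_hand_formula():
    x = np.array([1.0, 2.0, 3.0])
    y = np.array([1.0, 2.0, 4.0])
    zx, zy = x - x.mean(), y - y.mean()
    hand = (zx @ zy) / np.sqrt((zx @ zx) * (zy @ zy))
    out = _corr_df(x, y)
    assert np.max(np.abs(out["r"] - hand)) < 1e-10
    assert hand == pytest.approx(0.982, abs=5e-4)


def test_pearson_degenerate_flagged():
    out = _corr_df([2.0, 2.0, 2.0], [1.0, 2.0, 3.0])
    assert out["degenerate"].all()
    assert out["r"].isna().all()


def test_pearson_needs_three_units():
    with pytest.raises(PSRError, match="3"):
        _corr_df([1.0, 2.0], [1.0, 2.0])


def test_fig5_sign_pattern_on_default_region(default_run):
    _, outdir, _ = default_run
    corr = pd.read_csv(outdir / "psr_correlations.csv")
    for e in ("t0", "t1"):
        sub = corr[corr["epoch"] == e].set_index(["composite", "indicator"])
        for ind in ("npp", "evi", "et", "carbon"):
            assert sub.loc[("response", ind), "r"] > 0
        assert sub.loc[("pressure", "cn"), "r"] > 0
        assert sub.loc[("pressure", "lcr"), "r"] > 0
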