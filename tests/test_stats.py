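"""OLS layer, VIF screening, and 3-set variance partitioning."""

import numpy as np
import pandas as pd
import pytest

from elevgrad import (
    ElevgradError,
    adjusted_r2,
    ols_regress,
    partition_fractions,
    variance_inflation,
    variance_partition3,
    vif_screen,
)


def normal_equations_oracle(y, X):
    """Textbook (X'X)^-1 X'y fit with plain R^2, independent of statsmodels."""
    D = np.column_stack([np.ones(len(y)), X])
    beta = np.linalg.solve(D.T @ D, D.T @ y)
    resid = y - D @ beta
    ss_res = float(resid @ resid)
    ss_tot = float(((y - y.mean()) ** 2).sum())
    return beta, 1.0 - ss_res / ss_tot


def test_exact_line():
    x = np.arange(10.0)
    res = ols_regress(2 * x, pd.DataFrame({"x": x}))
    assert res.r2 == pytest.approx(1.0)
    assert res.params.loc["x", "estimate"] == pytest.approx(2.0)
    assert res.params.loc["const", "estimate"] == pytest.approx(0.0, abs=1e-10)


def test_exact_parabola_degree2():
    x = np.arange(1.0, 10.0)
    res = ols_regress((x - 5) ** 2, pd.DataFrame({"x": x}), degree=2)
    assert res.r2 == pytest.approx(1.0)


def test_matches_normal_equations_oracle(rng):
    n = 60
    X = pd.DataFrame(rng.normal(size=(n, 3)), columns=list("xyz"))
    y = rng.normal(size=n)
    for degree in (1, 2):
        res = ols_regress(y, X, degree=degree)
        D = X.copy()
        if degree == 2:
            for c in list(X.columns):
                D[f"{c}^2"] = X[c] ** 2
        beta, r2 = normal_equations_oracle(y, D.to_numpy())
        assert res.r2 == pytest.approx(r2, abs=1e-8)
        assert np.allclose(res.params["estimate"].to_numpy(), beta, atol=1e-8)
        assert res.adj_r2 == pytest.approx(
            adjusted_r2(r2, n, D.shape[1]), abs=1e-10
        )


def test_standardization_invariance(rng):
    n = 40
    X = pd.DataFrame(rng.normal(size=(n, 2)) * [10, 0.1] + [5, -3],
                     columns=["a", "b"])
    y = X["a"] * 0.5 - X["b"] * 2 + rng.normal(size=n)
    raw = ols_regress(y, X)
    std = ols_regress(y, X, standardize=True)
    assert std.r2 == pytest.approx(raw.r2, abs=1e-12)
    assert std.f_pvalue == pytest.approx(raw.f_pvalue, abs=1e-12)
    assert not np.allclose(std.params["estimate"], raw.params["estimate"])


def test_missing_rows_dropped(caplog, rng):
    X = pd.DataFrame({"x": np.arange(10.0)})
    y = 2 * X["x"]
    y[3] = np.nan
    with caplog.at_level("WARNING", logger="elevgrad"):
        res = ols_regress(y, X)
    assert res.n == 9
    assert any("dropped 1" in r.message for r in caplog.records)


def test_singular_design_names_columns(rng):
    x = rng.normal(size=30)
    X = pd.DataFrame({"x1": x, "x2": 2 * x})
    with pytest.raises(ElevgradError, match="x2"):
        ols_regress(rng.normal(size=30), X)


def test_vif_orthogonal_and_duplicate(rng):
    n = 200
    a = rng.normal(size=n)
    b = rng.normal(size=n)
    X = pd.DataFrame({"a": a, "b": b})
    retained, vifs = vif_screen(X)
    assert retained == ["a", "b"]
    assert vifs["a"] == pytest.approx(1.0, abs=0.05)

    X2 = pd.DataFrame({"a": a, "b": b, "a_copy": a})
    retained2, _ = vif_screen(X2)
    assert "a" in retained2 and "a_copy" not in retained2


def test_vif_matches_oracle(rng):
    n = 500
    z = rng.normal(size=n)
    X = pd.DataFrame(
        {
            "x1": z + 0.5 * rng.normal(size=n),
            "x2": z + 0.5 * rng.normal(size=n),
            "x3": rng.normal(size=n),
        }
    )
    for col in X.columns:
        others = X.drop(columns=col).to_numpy()
        _, r2 = normal_equations_oracle(X[col].to_numpy(), others)
        assert variance_inflation(X, col) == pytest.approx(1 / (1 - r2), rel=1e-8)


def test_partition_fractions_hand_example():
    """Inclusion-exclusion on the seven submodel adjusted R^2 values."""
    fr = partition_fractions(0.5, 0.4, 0.3, 0.6, 0.6, 0.5, 0.65)
    assert fr["a"] == pytest.approx(0.15)
    assert fr["b"] == pytest.approx(0.05)
    assert fr["c"] == pytest.approx(0.05)
    assert fr["d"] == pytest.approx(0.15)
    assert fr["e"] == pytest.approx(0.05)
    assert fr["f"] == pytest.approx(0.05)
    assert fr["g"] == pytest.approx(0.15)
    assert sum(fr[k] for k in "abcdefg") == pytest.approx(0.65)


def test_varpart_sums_to_full_model(rng):
    n = 60
    A = pd.DataFrame({"a": rng.normal(size=n)})
    B = pd.DataFrame({"b": rng.normal(size=n) + 0.5 * A["a"]})
    C = pd.DataFrame({"c": rng.normal(size=n)})
    y = A["a"] + B["b"] - C["c"] + rng.normal(size=n)
    vp = variance_partition3(y, A, B, C)
    full = ols_regress(y, pd.concat([A, B, C], axis=1)).adj_r2
    assert vp.explained == pytest.approx(full, abs=1e-10)
    assert vp.h == pytest.approx(1 - full, abs=1e-10)


def test_varpart_identical_sets(rng):
    n = 50
    A = pd.DataFrame({"a": rng.normal(size=n)})
    y = 2 * A["a"] + rng.normal(size=n)
    vp = variance_partition3(y, A, A.copy(), A.copy())
    assert vp.a == pytest.approx(0.0, abs=1e-12)
    assert vp.b == pytest.approx(0.0, abs=1e-12)
    assert vp.c == pytest.approx(0.0, abs=1e-12)
    assert vp.d == pytest.approx(0.0, abs=1e-12)
    assert vp.e == pytest.approx(0.0, abs=1e-12)
    assert vp.f == pytest.approx(0.0, abs=1e-12)
    assert vp.g == pytest.approx(ols_regress(y, A).adj_r2, abs=1e-12)


def test_varpart_orthogonal_predictors(rng):
    """With orthogonal predictors the shared fractions vanish."""
    n = 1000
    Q, _ = np.linalg.qr(rng.normal(size=(n, 3)))
    Q *= np.sqrt(n)  # unit variance, exactly orthogonal columns
    A = pd.DataFrame({"a": Q[:, 0]})
    B = pd.DataFrame({"b": Q[:, 1]})
    C = pd.DataFrame({"c": Q[:, 2]})
    y = 1.0 * A["a"] + 0.8 * B["b"] + 0.6 * C["c"] + rng.normal(size=n)
    vp = variance_partition3(y, A, B, C)
    for shared in (vp.d, vp.e, vp.f, vp.g):
        assert abs(shared) < 0.02
    assert abs(vp.a - ols_regress(y, A).adj_r2) < 0.02
    assert abs(vp.b - ols_regress(y, B).adj_r2) < 0.02
    assert abs(vp.c - ols_regress(y, C).adj_r2) < 0.02
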