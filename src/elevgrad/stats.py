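"""Regression layer: OLS fits, VIF screening, and 3-set variance partitioning.

Simple and polynomial (degree 2) ordinary least squares with optional
predictor standardization; variance-inflation-factor screening of
multicollinear predictors; and the classical three-set variance
partitioning of adjusted R^2 by inclusion-exclusion over the seven
submodels (the vegan ``varpart`` decomposition).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .core_io import ElevgradError

logger = logging.getLogger("elevgrad")


@dataclass(frozen=True)
class RegressionResult:
    """An OLS fit: coefficient table, fit statistics, optional VIFs."""

    response: str
    predictors: tuple[str, ...]
    degree: int
    params: pd.DataFrame  # index term; columns estimate, se, t, p
    r2: float
    adj_r2: float
    f_pvalue: float
    resid_se: float
    df_resid: int
    n: int
    vif: dict[str, float] | None = None
    standardized: bool = False


@dataclass(frozen=True)
class VariancePartition:
    """Pure/shared adjusted-R^2 fractions of three predictor sets.

    a, b, c are the pure fractions of sets A, B, C; d = shared A&B,
    e = shared B&C, f = shared A&C; g = shared by all three; h is the
    residual.  Raw fractions can be slightly negative (a known property of
    adjusted R^2); ``truncated`` clips them at zero for display.
    """

    labels: tuple[str, str, str]
    a: float
    b: float
    c: float
    d: float
    e: float
    f: float
    g: float
    h: float
    truncated: dict[str, float] = field(default_factory=dict)

    @property
    def explained(self) -> float:
        return self.a + self.b + self.c + self.d + self.e + self.f + self.g


def _design(
    X: pd.DataFrame, degree: int, standardize: bool
) -> pd.DataFrame:
    """Expand the predictor table to the model design (no intercept column)."""
    X = X.astype(float).copy()
    if standardize:
        X = (X - X.mean()) / X.std(ddof=1)
    if degree == 2:
        for c in list(X.columns):
            X[f"{c}^2"] = X[c] ** 2
    elif degree != 1:
        raise ElevgradError(f"degree must be 1 or 2, got {degree}")
    return X


def adjusted_r2(r2: float, n: int, p: int) -> float:
    """Ezekiel correction: 1 - (1 - R^2)(n - 1)/(n - p - 1)."""
    if n - p - 1 <= 0:
        raise ElevgradError(f"not enough rows (n={n}) for {p} predictors")
    return 1.0 - (1.0 - r2) * (n - 1) / (n - p - 1)


def ols_regress(
    y,
    X: pd.DataFrame,
    degree: int = 1,
    standardize: bool = False,
    response: str = "y",
) -> RegressionResult:
    """OLS with intercept; degree 2 adds squared terms of each predictor.

    Rows where the response or any predictor is missing are dropped (the
    drop count is logged).  A singular design raises an error naming the
    collinear columns.
    """
    X = pd.DataFrame(X)
    y = pd.Series(np.asarray(y, dtype=float), index=X.index, name=response)
    keep = y.notna() & X.notna().all(axis=1)
    dropped = int((~keep).sum())
    if dropped:
        logger.warning("ols_regress(%s): dropped %d rows with missing values",
                       response, dropped)
    y, X = y[keep], X[keep]
    D = _design(X, degree, standardize)
    n, p = D.shape
    if n <= p + 1:
        raise ElevgradError(f"need more rows ({n}) than parameters ({p + 1})")
    if np.linalg.matrix_rank(np.column_stack([np.ones(n), D.to_numpy()])) < p + 1:
        corr = D.corr().abs()
        np.fill_diagonal(corr.values, 0.0)
        bad = sorted(set(corr.columns[(corr > 1 - 1e-12).any()]))
        raise ElevgradError(f"singular design; collinear columns: {bad}")
    model = sm.OLS(y.to_numpy(), sm.add_constant(D)).fit()
    params = pd.DataFrame(
        {
            "estimate": model.params,
            "se": model.bse,
            "t": model.tvalues,
            "p": model.pvalues,
        }
    )
    vif = None
    if degree == 1 and p >= 2:
        vif = {c: variance_inflation(D, c) for c in D.columns}
    return RegressionResult(
        response=response,
        predictors=tuple(X.columns),
        degree=degree,
        params=params,
        r2=float(model.rsquared),
        adj_r2=float(model.rsquared_adj),
        f_pvalue=float(model.f_pvalue),
        resid_se=float(np.sqrt(model.mse_resid)),
        df_resid=int(model.df_resid),
        n=n,
        vif=vif,
        standardized=standardize,
    )


def variance_inflation(X: pd.DataFrame, column: str) -> float:
    """VIF of one predictor: 1/(1 - R^2) from regressing it on the others."""
    others = [c for c in X.columns if c != column]
    if not others:
        return 1.0
    D = sm.add_constant(X[others].to_numpy(dtype=float))
    yj = X[column].to_numpy(dtype=float)
    r2 = sm.OLS(yj, D).fit().rsquared
    if r2 >= 1.0 - 1e-12:
        return float("inf")
    return float(1.0 / (1.0 - r2))


def vif_screen(
    X: pd.DataFrame, threshold: float = 3.0
) -> tuple[list[str], dict[str, float]]:
    """Greedy VIF screen: drop the worst predictor until all VIFs < threshold.

    Perfectly collinear pairs drop the later column (with a warning).  The
    returned VIFs are computed on the retained set.
    """
    X = pd.DataFrame(X).astype(float)
    if X.shape[1] < 2:
        raise ElevgradError("vif_screen needs at least 2 predictors")
    retained = list(X.columns)
    while len(retained) >= 2:
        vifs = {c: variance_inflation(X[retained], c) for c in retained}
        worst = max(vifs.values())
        if worst < threshold:
            return retained, vifs
        # among the maximal VIFs, drop the later column
        offenders = [c for c in retained if vifs[c] == worst]
        victim = offenders[-1]
        if np.isinf(worst):
            logger.warning("vif_screen: dropping perfectly collinear %r", victim)
        else:
            logger.warning("vif_screen: dropping %r (VIF=%.2f)", victim, worst)
        retained.remove(victim)
    return retained, {retained[0]: 1.0}


def _adj_r2_of(y: pd.Series, D: pd.DataFrame) -> float:
    model = sm.OLS(y.to_numpy(), sm.add_constant(D.to_numpy(dtype=float))).fit()
    return float(model.rsquared_adj)


def partition_fractions(
    RA: float, RB: float, RC: float,
    RAB: float, RAC: float, RBC: float, RABC: float,
) -> dict[str, float]:
    """Inclusion-exclusion decomposition of the seven submodel R^2 values.

    Pure fractions a, b, c; pairwise-only shared d (A&B), e (B&C), f (A&C);
    three-way shared g; residual h.  The seven explained fractions sum to
    RABC identically.
    """
    a = RABC - RBC
    b = RABC - RAC
    c = RABC - RAB
    g = RA + RB + RC - RAB - RAC - RBC + RABC
    d = RA + RB - RAB - g
    e = RB + RC - RBC - g
    f = RA + RC - RAC - g
    return {"a": a, "b": b, "c": c, "d": d, "e": e, "f": f, "g": g,
            "h": 1.0 - RABC}


def variance_partition3(
    y,
    A: pd.DataFrame,
    B: pd.DataFrame,
    C: pd.DataFrame,
    labels: tuple[str, str, str] = ("A", "B", "C"),
) -> VariancePartition:
    """Partition adjusted R^2 over three predictor sets by inclusion-exclusion.

    Fits the seven OLS models {A},{B},{C},{AB},{AC},{BC},{ABC}; with
    R(.) the adjusted R^2:

        a = R(ABC) - R(BC)            (pure A)
        b = R(ABC) - R(AC)            (pure B)
        c = R(ABC) - R(AB)            (pure C)
        g = R(A)+R(B)+R(C) - R(AB)-R(AC)-R(BC) + R(ABC)
        d = R(A)+R(B) - R(AB) - g     (shared A&B only)
        e = R(B)+R(C) - R(BC) - g     (shared B&C only)
        f = R(A)+R(C) - R(AC) - g     (shared A&C only)
        h = 1 - R(ABC)

    The seven fractions sum to R(ABC) exactly (algebraic identity).
    """
    A, B, C = (pd.DataFrame(Z).astype(float) for Z in (A, B, C))
    y = pd.Series(np.asarray(y, dtype=float), index=A.index)
    keep = y.notna() & A.notna().all(axis=1) & B.notna().all(axis=1) \
        & C.notna().all(axis=1)
    dropped = int((~keep).sum())
    if dropped:
        logger.warning("variance_partition3: dropped %d rows with missing values",
                       dropped)
    y = y[keep]
    A, B, C = A[keep], B[keep], C[keep]

    def cat(*parts):
        return pd.concat(parts, axis=1)

    RA = _adj_r2_of(y, A)
    RB = _adj_r2_of(y, B)
    RC = _adj_r2_of(y, C)
    RAB = _adj_r2_of(y, cat(A, B))
    RAC = _adj_r2_of(y, cat(A, C))
    RBC = _adj_r2_of(y, cat(B, C))
    RABC = _adj_r2_of(y, cat(A, B, C))

    fr = partition_fractions(RA, RB, RC, RAB, RAC, RBC, RABC)
    truncated = {k: max(v, 0.0) for k, v in fr.items() if k != "h"}
    return VariancePartition(
        labels=tuple(labels), truncated=truncated, **fr,
    )
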