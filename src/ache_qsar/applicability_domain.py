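"""Leverage-based applicability domain and Williams-plot classification.

A compound's leverage h_i = x_i^T (X^T X)^{-1} x_i measures its remoteness in
descriptor space relative to the training design; compounds beyond the warning
leverage h* = 3(p+1)/n exert disproportionate influence on the model, while
compounds with |standardized residual| > 3 are response outliers.  The design
is augmented with an intercept column (hence p+1), and a Moore-Penrose
pseudoinverse is used so near-collinear fingerprint designs remain computable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

CATEGORIES = ("in_domain", "high_leverage", "outlier", "high_leverage_outlier")


@dataclass
class LeverageResult:
    """Per-compound leverage diagnostics for a Williams plot."""

    h: np.ndarray
    h_star: float
    std_resid: np.ndarray
    category: list[str]
    is_train: np.ndarray  # boolean mask: internal (True) vs external rows

    def counts(self) -> dict[str, int]:
        out = {c: 0 for c in CATEGORIES}
        for c in self.category:
            out[c] += 1
        return out


def _augment(X: np.ndarray, add_intercept: bool) -> np.ndarray:
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if add_intercept:
        return np.hstack([np.ones((X.shape[0], 1)), X])
    return X


def hat_diagonals(
    X_train: np.ndarray,
    X_query: np.ndarray | None = None,
    add_intercept: bool = True,
) -> np.ndarray:
    """Diagonal of the hat (projection) matrix for training or query rows.

    The training design is augmented with a column of ones unless
    ``add_intercept=False``; (X^T X)^{-1} is formed with a pseudoinverse, so
    rank-deficient designs yield the minimum-norm projection.  When
    ``X_query`` is given, its rows are evaluated against the training inverse.
    """
    Xa = _augment(X_train, add_intercept)
    n, p = Xa.shape
    if n <= p:
        # strictly more rows than (augmented) columns are required for the
        # inverse to define a proper projection with h <= 1
        raise ValueError(f"underdetermined design: n={n} rows, p={p} columns")
    XtX_inv = np.linalg.pinv(Xa.T @ Xa)
    Q = _augment(X_query, add_intercept) if X_query is not None else Xa
    return np.einsum("ij,jk,ik->i", Q, XtX_inv, Q)


def warning_leverage(p: int, n: int) -> float:
    """Warning leverage h* = 3(p+1)/n for p descriptors and n training rows."""
    if n <= 0 or p < 1:
        raise ValueError("need n > 0 and p >= 1")
    return 3.0 * (p + 1) / n


def standardized_residuals(y, yhat) -> np.ndarray:
    """Residuals divided by their own sample standard deviation."""
    y = np.asarray(y, dtype=float)
    yhat = np.asarray(yhat, dtype=float)
    if len(y) < 3:
        raise ValueError("need at least 3 observations")
    resid = y - yhat
    sd = np.std(resid, ddof=1)
    if sd == 0:
        raise ValueError("zero residual spread: standardized residuals undefined")
    return resid / sd


def williams_classify(h, std_resid, h_star: float, limit: float = 3.0) -> list[str]:
    """Four-way Williams classification of each compound.

    Outliers have |standardized residual| > ``limit``; high-leverage compounds
    have h > h* (they influence the model strongly yet need not be outliers,
    as their residual may be small).
    """
    h = np.asarray(h, dtype=float)
    s = np.asarray(std_resid, dtype=float)
    if len(h) != len(s):
        raise ValueError("h and std_resid are not aligned")
    out = []
    for hi, si in zip(h, s):
        lev = hi > h_star
        res = abs(si) > limit
        if lev and res:
            out.append("high_leverage_outlier")
        elif lev:
            out.append("high_leverage")
        elif res:
            out.append("outlier")
        else:
            out.append("in_domain")
    return out


def williams_analysis(
    X_train,
    y_train,
    yhat_train,
    X_test=None,
    y_test=None,
    yhat_test=None,
    limit: float = 3.0,
) -> LeverageResult:
    """Full leverage analysis for one fitted split.

    Internal and external standardized residuals are scaled by their own set's
    residual SD; h* uses the training dimensions (raw descriptor count p and
    internal n).
    """
    X_train = np.atleast_2d(np.asarray(X_train, dtype=float))
    n, p = X_train.shape
    h_star = warning_leverage(p, n)
    h_tr = hat_diagonals(X_train)
    s_tr = standardized_residuals(y_train, yhat_train)
    h, s = h_tr, s_tr
    is_train = np.ones(len(h_tr), dtype=bool)
    if X_test is not None:
        h_te = hat_diagonals(X_train, X_test)
        s_te = standardized_residuals(y_test, yhat_test)
        h = np.concatenate([h_tr, h_te])
        s = np.concatenate([s_tr, s_te])
        is_train = np.concatenate([is_train, np.zeros(len(h_te), dtype=bool)])
    return LeverageResult(
        h=h,
        h_star=h_star,
        std_resid=s,
        category=williams_classify(h, s, h_star, limit),
        is_train=is_train,
    )
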