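"""Scalar validation metrics for QSAR regression models.

Implements the usual external-validation battery: squared Pearson correlation
R2, RMSE, the predictive Q2 statistic (1 - PRESS/SS with the training-set mean
as reference), the rm2 / delta-rm2 pair penalizing divergence between the
with-intercept and through-origin observed-vs-predicted fits, and the
Y-scrambling permutation test with its iR2/iQ2 intercepts.

Acceptability conventions wired into :func:`acceptability`: rm2 > 0.5,
delta rm2 < 0.2, negative iQ2, and R2-Q2 margins below 0.3.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np


def r_squared(y, yhat) -> float:
    """Squared Pearson correlation between observed and predicted values."""
    y = np.asarray(y, dtype=float)
    yhat = np.asarray(yhat, dtype=float)
    if len(y) < 3:
        raise ValueError("need at least 3 observations")
    if np.std(y) == 0:
        raise ValueError("R2 undefined for constant observations")
    if np.std(yhat) == 0:
        return 0.0
    r = np.corrcoef(y, yhat)[0, 1]
    return float(r * r)


def rmse(y, yhat) -> float:
    """Root mean squared error."""
    y = np.asarray(y, dtype=float)
    yhat = np.asarray(yhat, dtype=float)
    if len(y) == 0:
        raise ValueError("empty input")
    if len(y) != len(yhat):
        raise ValueError("length mismatch")
    return float(np.sqrt(np.mean((y - yhat) ** 2)))


def q2_external(y_test, yhat_test, ybar_train: float) -> float:
    """Predictive Q2 = 1 - sum((y-yhat)^2) / sum((y-ybar_train)^2).

    The denominator references the *training-set* mean (Golbraikh-Tropsha
    convention), so the training-mean predictor scores exactly 0 and anything
    worse goes negative.
    """
    y = np.asarray(y_test, dtype=float)
    yhat = np.asarray(yhat_test, dtype=float)
    if len(y) < 3:
        raise ValueError("need at least 3 test observations")
    ss = np.sum((y - ybar_train) ** 2)
    if ss == 0:
        raise ValueError("zero reference sum of squares")
    return float(1.0 - np.sum((y - yhat) ** 2) / ss)


def _r0_squared(y, yhat) -> float:
    # through-origin observed-vs-predicted determination: slope k = sum(y*yhat)/sum(yhat^2)
    den = np.sum(yhat**2)
    if den == 0:
        raise ValueError("zero sum of squared predictions")
    k = np.sum(y * yhat) / den
    ss_res = np.sum((y - k * yhat) ** 2)
    ss_tot = np.sum((y - y.mean()) ** 2)
    return float(1.0 - ss_res / ss_tot)


def rm2_metrics(y, yhat) -> tuple[float, float]:
    """The (average rm2, delta rm2) robustness pair.

    rm2 = r2 * (1 - sqrt(|r2 - r0_2|)) where r0_2 is the through-origin
    determination; the reversed variant swaps the roles of observed and
    predicted; the average and absolute difference of the two are returned.
    """
    y = np.asarray(y, dtype=float)
    yhat = np.asarray(yhat, dtype=float)
    r2 = r_squared(y, yhat)
    rm2_fwd = r2 * (1.0 - np.sqrt(abs(r2 - _r0_squared(y, yhat))))
    rm2_rev = r2 * (1.0 - np.sqrt(abs(r2 - _r0_squared(yhat, y))))
    return float((rm2_fwd + rm2_rev) / 2.0), float(abs(rm2_fwd - rm2_rev))


@dataclass
class MetricsReport:
    r2: float
    rmse: float
    q2: float
    rm2_avg: float
    delta_rm2: float


def external_metrics(y_test, yhat_test, ybar_train: float) -> MetricsReport:
    """Full external-set metric block for one fitted split."""
    rm2_avg, delta = rm2_metrics(y_test, yhat_test)
    return MetricsReport(
        r2=r_squared(y_test, yhat_test),
        rmse=rmse(y_test, yhat_test),
        q2=q2_external(y_test, yhat_test, ybar_train),
        rm2_avg=rm2_avg,
        delta_rm2=delta,
    )


# ---------------------------------------------------------------------------
# Y-scrambling


@dataclass
class ScramblingReport:
    """Permutation-null summary: per-permutation points and the intercepts."""

    r_perm: np.ndarray  # correlation of each permuted response with the true one
    r2: np.ndarray  # training R2 of the model refit on the permuted response
    q2: np.ndarray  # cross-validated Q2 of the same refit
    iR2: float
    iQ2: float
    n_perm: int

    @property
    def mean_scrambled_q2(self) -> float:
        # last point is the unscrambled model; exclude it from the null mean
        return float(np.mean(self.q2[:-1]))

    @property
    def mean_scrambled_r2(self) -> float:
        return float(np.mean(self.r2[:-1]))


def _intercept(x: np.ndarray, z: np.ndarray) -> float:
    slope, intercept = np.polyfit(x, z, 1)
    return float(intercept)


def y_scramble(
    X,
    y,
    fit_and_score: Callable[[np.ndarray, np.ndarray, int], tuple[float, float]] | None = None,
    n_perm: int = 100,
    seed: int = 0,
    config=None,
) -> ScramblingReport:
    """Y-scrambling test on one fixed modeling set.

    For each permutation the response is shuffled and the model protocol is
    refit from scratch, recording the training R2 and cross-validated Q2; the
    unscrambled model is appended as the point at r = 1.  iR2 and iQ2 are the
    intercepts of least-squares lines of R2 and Q2 versus |r_perm|.  A
    negative, near-zero iQ2 indicates the unscrambled model's performance does
    not stem from chance correlation.

    ``fit_and_score(X, y_perm, seed) -> (R2_train, Q2_cv)`` may be supplied to
    control the refitting; by default the protocol forest from
    :mod:`ache_qsar.modeling` is used with ``config``.
    """
    import warnings

    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if n_perm < 2:
        raise ValueError("need at least 2 permutations")
    if n_perm < 10:
        warnings.warn("fewer than 10 permutations: intercept estimates are unstable")

    if fit_and_score is None:
        from .modeling import ProtocolConfig, cross_validate, fit_rf

        cfg = config if config is not None else ProtocolConfig()

        def fit_and_score(Xm, ym, s):
            model = fit_rf(Xm, ym, cfg, seed=s)
            r2_tr = r_squared(ym, model.predict(Xm))
            q2_cv, _ = cross_validate(Xm, ym, cfg, seed=s)
            return r2_tr, q2_cv

    rng = np.random.default_rng(seed)
    r_perm, r2s, q2s = [], [], []
    for j in range(n_perm):
        y_perm = rng.permutation(y)
        r = float(np.corrcoef(y, y_perm)[0, 1])
        r2_j, q2_j = fit_and_score(X, y_perm, seed + j)
        r_perm.append(r)
        r2s.append(r2_j)
        q2s.append(q2_j)
    # the unscrambled model anchors the regression at r = 1
    r2_true, q2_true = fit_and_score(X, y, seed + n_perm)
    r_perm.append(1.0)
    r2s.append(r2_true)
    q2s.append(q2_true)

    r_abs = np.abs(np.array(r_perm))
    r2_arr, q2_arr = np.array(r2s), np.array(q2s)
    return ScramblingReport(
        r_perm=np.array(r_perm),
        r2=r2_arr,
        q2=q2_arr,
        iR2=_intercept(r_abs, r2_arr),
        iQ2=_intercept(r_abs, q2_arr),
        n_perm=n_perm,
    )


# ---------------------------------------------------------------------------
# acceptability flags


@dataclass
class Acceptability:
    rm2_ok: bool
    delta_rm2_ok: bool
    iq2_ok: bool | None
    margin_ok: bool | None
    flags: dict = field(default_factory=dict)

    @property
    def acceptable(self) -> bool:
        checks = [self.rm2_ok, self.delta_rm2_ok]
        checks += [c for c in (self.iq2_ok, self.margin_ok) if c is not None]
        return all(checks)


def acceptability(
    rm2_avg: float,
    delta_rm2: float,
    iq2: float | None = None,
    margin: float | None = None,
    margin_limit: float = 0.3,
) -> Acceptability:
    """Apply the standard acceptance thresholds: rm2 > 0.5, delta rm2 < 0.2,
    iQ2 < 0, and an R2-Q2 margin under ~0.3."""
    return Acceptability(
        rm2_ok=rm2_avg > 0.5,
        delta_rm2_ok=delta_rm2 < 0.2,
        iq2_ok=None if iq2 is None else iq2 < 0,
        margin_ok=None if margin is None else margin < margin_limit,
        flags={"rm2_avg": rm2_avg, "delta_rm2": delta_rm2, "iq2": iq2, "margin": margin},
    )
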