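"""Resampled random-forest benchmarking protocol.

The protocol guards against split bias by repeating the whole modeling
exercise over many independent 80/20 partitions: per split, a regression
forest is fitted on the internal 80%, assessed by 10-fold cross-validation
inside that internal set, and challenged on the held-out external 20%.
Reported statistics are means and sample SDs over the splits.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np
from sklearn.ensemble import RandomForestRegressor
from sklearn.model_selection import KFold

from .validation_stats import q2_external, r_squared, rmse

METRICS = ("R2_tr", "RMSE_tr", "Q2_cv", "RMSE_cv", "Q2_ext", "RMSE_ext")


@dataclass(frozen=True)
class ProtocolConfig:
    """Knobs of the resampling protocol.

    ``rf_mtry`` follows the usual regression-forest default of sqrt(p)
    candidate features per split when set to "sqrt"; an integer fixes it.
    ``compute_cv=False`` skips the internal cross-validation (for studies that
    only need external statistics, saving cv_folds model fits per split).
    """

    n_splits: int = 100
    train_fraction: float = 0.8
    cv_folds: int = 10
    rf_trees: int = 500
    rf_mtry: int | str = "sqrt"
    base_seed: int = 0
    compute_cv: bool = True

    def __post_init__(self):
        if not (0.0 < self.train_fraction < 1.0):
            raise ValueError("train_fraction must be in (0, 1)")
        if self.n_splits < 1:
            raise ValueError("n_splits must be >= 1")
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")


@dataclass
class ModelRun:
    """Metrics and importances of one split of the protocol."""

    split_index: int
    train_ids: np.ndarray
    test_ids: np.ndarray
    R2_tr: float
    RMSE_tr: float
    Q2_cv: float
    RMSE_cv: float
    Q2_ext: float
    RMSE_ext: float
    importance: dict[str, float] = field(default_factory=dict)


@dataclass
class BenchmarkReport:
    """Mean +/- SD aggregation over the protocol's runs."""

    n_runs: int
    mean: dict[str, float]
    sd: dict[str, float]
    margin_cv: float  # mean R2_tr - mean Q2_cv
    margin_ext: float  # mean R2_tr - mean Q2_ext
    mean_importance: dict[str, float] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "n_runs": self.n_runs,
            "mean": self.mean,
            "sd": self.sd,
            "margin_cv": self.margin_cv,
            "margin_ext": self.margin_ext,
            "mean_importance": self.mean_importance,
        }


def split_data(ids: Sequence, fraction: float = 0.8, seed: int = 0):
    """Uniform random train/test partition without replacement.

    Training size is round(fraction * n); deterministic for a given seed.
    """
    ids = np.asarray(ids)
    n = len(ids)
    if n < 5:
        raise ValueError("need at least 5 ids to split")
    n_train = int(round(fraction * n))
    if n_train == 0 or n_train == n:
        raise ValueError(f"fraction {fraction} yields an empty train or test side")
    perm = np.random.default_rng(seed).permutation(n)
    return ids[perm[:n_train]], ids[perm[n_train:]]


def _mtry(config: ProtocolConfig, p: int):
    if config.rf_mtry == "sqrt":
        return "sqrt"
    return int(min(config.rf_mtry, p))


def fit_rf(X_train: np.ndarray, y_train: np.ndarray, config: ProtocolConfig, seed: int = 0) -> RandomForestRegressor:
    """Fit a seeded regression forest per the protocol configuration."""
    X_train = np.asarray(X_train, dtype=float)
    y_train = np.asarray(y_train, dtype=float)
    if not (np.isfinite(X_train).all() and np.isfinite(y_train).all()):
        raise ValueError("non-finite values in X or y")
    if len(y_train) < 10:
        raise ValueError("need at least 10 training samples")
    model = RandomForestRegressor(
        n_estimators=config.rf_trees,
        max_features=_mtry(config, X_train.shape[1]),
        random_state=seed,
        n_jobs=1,
    )
    model.fit(X_train, y_train)
    return model


def cross_validate(
    X: np.ndarray,
    y: np.ndarray,
    config: ProtocolConfig,
    seed: int = 0,
    model_factory: Callable | None = None,
) -> tuple[float, float]:
    """K-fold cross-validation with pooled out-of-fold predictions.

    Returns (Q2_cv, RMSE_cv) where Q2 uses 1 - PRESS/SS against the mean of
    the full internal set, computed on the assembled out-of-fold prediction
    vector (pooled, not averaged per fold).  ``model_factory(seed)`` may
    inject any estimator with fit/predict; the protocol forest is the default.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(y)
    if n < config.cv_folds:
        raise ValueError("fewer samples than folds")
    if n // config.cv_folds < 2:
        raise ValueError("a fold would hold fewer than 2 samples")
    oof = np.empty(n)
    kf = KFold(n_splits=config.cv_folds, shuffle=True, random_state=seed % (2**32))
    for fold_train, fold_test in kf.split(X):
        if model_factory is not None:
            model = model_factory(seed)
            model.fit(X[fold_train], y[fold_train])
        else:
            model = fit_rf(X[fold_train], y[fold_train], config, seed=seed)
        oof[fold_test] = model.predict(X[fold_test])
    return q2_external(y, oof, float(y.mean())), rmse(y, oof)


def run_protocol(
    X: np.ndarray,
    y: np.ndarray,
    config: ProtocolConfig,
    col_ids: Sequence[str] | None = None,
) -> list[ModelRun]:
    """Run the full resampled protocol: split, fit, CV, external prediction.

    Split i uses seed ``base_seed + i`` so any single split can be re-run in
    isolation.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(X) != len(y):
        raise ValueError("X and y are not aligned")
    ids = np.arange(len(y))
    keys = [str(c) for c in col_ids] if col_ids is not None else [str(j) for j in range(X.shape[1])]
    runs: list[ModelRun] = []
    for i in range(config.n_splits):
        seed = config.base_seed + i
        train_ids, test_ids = split_data(ids, config.train_fraction, seed=seed)
        X_tr, y_tr = X[train_ids], y[train_ids]
        X_te, y_te = X[test_ids], y[test_ids]
        model = fit_rf(X_tr, y_tr, config, seed=seed)
        yhat_tr = model.predict(X_tr)
        if config.compute_cv:
            q2_cv, rmse_cv = cross_validate(X_tr, y_tr, config, seed=seed)
        else:
            q2_cv, rmse_cv = np.nan, np.nan
        yhat_te = model.predict(X_te)
        runs.append(
            ModelRun(
                split_index=i,
                train_ids=train_ids,
                test_ids=test_ids,
                R2_tr=r_squared(y_tr, yhat_tr),
                RMSE_tr=rmse(y_tr, yhat_tr),
                Q2_cv=q2_cv,
                RMSE_cv=rmse_cv,
                Q2_ext=q2_external(y_te, yhat_te, float(y_tr.mean())),
                RMSE_ext=rmse(y_te, yhat_te),
                importance=dict(zip(keys, model.feature_importances_.tolist())),
            )
        )
    return runs


def aggregate(runs: Sequence[ModelRun]) -> BenchmarkReport:
    """Mean and sample SD of every metric over the runs, plus R2-Q2 margins."""
    if not runs:
        raise ValueError("no runs to aggregate")
    mean, sd = {}, {}
    for m in METRICS:
        vals = np.array([getattr(r, m) for r in runs], dtype=float)
        mean[m] = float(np.mean(vals))
        sd[m] = float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0
    keys = list(runs[0].importance)
    imp = {k: float(np.mean([r.importance[k] for r in runs])) for k in keys}
    return BenchmarkReport(
        n_runs=len(runs),
        mean=mean,
        sd=sd,
        margin_cv=mean["R2_tr"] - mean["Q2_cv"],
        margin_ext=mean["R2_tr"] - mean["Q2_ext"],
        mean_importance=imp,
    )


def importance_ranking(report: BenchmarkReport, top_k: int | None = None) -> list[str]:
    """Descriptor keys by descending mean importance; ties by key order."""
    keys = list(report.mean_importance)
    order = sorted(range(len(keys)), key=lambda j: (-report.mean_importance[keys[j]], j))
    ranked = [keys[j] for j in order]
    return ranked if top_k is None else ranked[:top_k]


def scaled(config: ProtocolConfig, **kwargs) -> ProtocolConfig:
    """A copy of the config with some fields replaced (convenience)."""
    return replace(config, **kwargs)
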