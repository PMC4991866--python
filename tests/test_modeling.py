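"""Resampling protocol: splits, forest fitting, CV, aggregation, importances."""

import numpy as np
import pytest

from ache_qsar.modeling import (
    METRICS,
    BenchmarkReport,
    ModelRun,
    ProtocolConfig,
    aggregate,
    cross_validate,
    fit_rf,
    importance_ranking,
    run_protocol,
    split_data,
)

FAST = ProtocolConfig(n_splits=2, rf_trees=60, cv_folds=5, base_seed=0)


class TestSplitData:
    @pytest.mark.parametrize("n,expected", [(2570, (2056, 514)), (10, (8, 2)), (101, (81, 20))])
    def test_sizes_follow_rounding(self, n, expected):
        tr, te = split_data(np.arange(n), 0.8, seed=1)
        assert (len(tr), len(te)) == expected

    def test_partition_is_disjoint_and_exhaustive(self):
        ids = np.arange(137)
        tr, te = split_data(ids, 0.8, seed=5)
        assert not set(tr) & set(te)
        assert sorted(np.concatenate([tr, te])) == list(ids)

    def test_same_seed_same_partition(self):
        ids = np.arange(50)
        assert np.array_equal(split_data(ids, 0.8, seed=9)[0], split_data(ids, 0.8, seed=9)[0])
        assert not np.array_equal(split_data(ids, 0.8, seed=9)[0], split_data(ids, 0.8, seed=10)[0])

    def test_too_few_ids_rejected(self):
        with pytest.raises(ValueError):
            split_data(np.arange(3), 0.8, seed=0)

    def test_degenerate_fraction_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            split_data(np.arange(20), 0.999999, seed=0)


class TestFitRF:
    def test_constant_response_predicted_exactly(self, rng):
        X = rng.normal(size=(30, 4))
        y = np.full(30, 5.5)
        model = fit_rf(X, y, FAST, seed=0)
        assert np.allclose(model.predict(X), 5.5)

    def test_single_informative_feature_takes_all_importance(self, rng):
        X = rng.normal(size=(100, 1))
        model = fit_rf(X, X[:, 0], FAST, seed=0)
        assert model.feature_importances_[0] == pytest.approx(1.0)

    def test_noiseless_planted_signal_near_interpolated(self, rng):
        from ache_qsar.validation_stats import r_squared

        X = rng.poisson(1.5, size=(500, 10)).astype(float)
        y = X[:, 0] * 2.0 + X[:, 3]
        model = fit_rf(X, y, ProtocolConfig(rf_trees=200), seed=1)
        assert r_squared(y, model.predict(X)) >= 0.95

    def test_nonfinite_rejected(self, rng):
        X = rng.normal(size=(20, 3))
        y = rng.normal(size=20)
        X[0, 0] = np.inf
        with pytest.raises(ValueError, match="non-finite"):
            fit_rf(X, y, FAST)


class _OracleModel:
    """Memorizes the global row -> response map; predicts perfectly."""

    def __init__(self, X, y):
        self.table = {tuple(row): yi for row, yi in zip(X, y)}

    def fit(self, X, y):
        return self

    def predict(self, X):
        return np.array([self.table[tuple(row)] for row in X])


class TestCrossValidate:
    def test_perfect_oracle_scores_one(self, rng):
        X = rng.normal(size=(60, 3))
        y = rng.normal(size=60)
        oracle = _OracleModel(X, y)
        q2, err = cross_validate(X, y, FAST, seed=0, model_factory=lambda s: oracle)
        assert q2 == pytest.approx(1.0) and err == pytest.approx(0.0)

    def test_permuted_response_has_no_cv_signal(self, rng):
        X = rng.poisson(1.5, size=(500, 10)).astype(float)
        y = rng.permutation(X[:, 0] * 2.0 + rng.normal(0, 0.5, 500))
        cfg = ProtocolConfig(rf_trees=100, cv_folds=5)
        q2, _ = cross_validate(X, y, cfg, seed=3)
        assert q2 <= 0.1

    def test_underfilled_fold_rejected(self, rng):
        X = rng.normal(size=(12, 2))
        with pytest.raises(ValueError, match="fold"):
            cross_validate(X, rng.normal(size=12), ProtocolConfig(cv_folds=10))


class TestRunProtocolAndAggregate:
    def test_single_split_protocol(self, rng):
        X = rng.poisson(1.0, size=(80, 5)).astype(float)
        y = X[:, 0] + rng.normal(0, 0.2, 80)
        cfg = ProtocolConfig(n_splits=1, rf_trees=50, cv_folds=4, base_seed=3)
        runs = run_protocol(X, y, cfg, col_ids=list("abcde"))
        assert len(runs) == 1
        run = runs[0]
        assert len(run.train_ids) == 64 and len(run.test_ids) == 16
        assert set(run.importance) == set("abcde")
        assert run.Q2_cv <= 1.0 and run.Q2_ext <= 1.0

    def test_training_beats_external_on_average(self, rng):
        X = rng.poisson(1.0, size=(150, 6)).astype(float)
        y = X[:, 1] * 1.5 + rng.normal(0, 0.7, 150)
        cfg = ProtocolConfig(n_splits=4, rf_trees=80, cv_folds=4, base_seed=0)
        agg = aggregate(run_protocol(X, y, cfg))
        assert agg.mean["R2_tr"] >= agg.mean["Q2_ext"]

    def test_compute_cv_off_leaves_cv_metrics_nan(self, rng):
        X = rng.normal(size=(60, 3))
        y = rng.normal(size=60)
        cfg = ProtocolConfig(n_splits=1, rf_trees=30, compute_cv=False)
        (run,) = run_protocol(X, y, cfg)
        assert np.isnan(run.Q2_cv) and np.isnan(run.RMSE_cv)

    def test_aggregate_hand_values(self):
        def mk(i, v):
            return ModelRun(i, np.arange(4), np.arange(4, 8),
                            R2_tr=v, RMSE_tr=v, Q2_cv=v, RMSE_cv=v, Q2_ext=v, RMSE_ext=v,
                            importance={"a": v})

        agg = aggregate([mk(0, 0.7), mk(1, 0.9)])
        for m in METRICS:
            assert agg.mean[m] == pytest.approx(0.8)
            assert agg.sd[m] == pytest.approx(0.1414, abs=1e-4)
        assert agg.margin_ext == pytest.approx(0.0)

    def test_identical_runs_have_zero_sd(self):
        run = ModelRun(0, np.arange(4), np.arange(4, 8), 0.9, 0.4, 0.8, 0.5, 0.8, 0.5, {"a": 1.0})
        agg = aggregate([run, run, run])
        assert all(agg.sd[m] == pytest.approx(0.0, abs=1e-12) for m in METRICS)


class TestImportance:
    def test_planted_features_recovered_in_top_ranks(self):
        from ache_qsar.synthetic import gen_count_matrix, gen_response, noise_for_ceiling

        X, cols = gen_count_matrix(600, 50, seed=4, correlation=0.1)
        planted = [(cols[i], w) for i, w in zip([2, 9, 17, 31, 46], [1.0, 0.9, 0.8, 0.7, 0.6])]
        sig = sum(w * X[:, cols.index(k)] for k, w in planted)
        y, _ = gen_response(X, planted, noise_for_ceiling(sig, 0.8), seed=5, col_ids=cols)
        cfg = ProtocolConfig(n_splits=2, rf_trees=150, base_seed=1, compute_cv=False)
        agg = aggregate(run_protocol(X, y, cfg, col_ids=cols))
        top5 = importance_ranking(agg, top_k=5)
        assert len(set(top5) & {k for k, _ in planted}) >= 4

    def test_single_feature_ranks_first(self):
        report = BenchmarkReport(1, {m: 0 for m in METRICS}, {m: 0 for m in METRICS},
                                 0, 0, mean_importance={"only": 1.0})
        assert importance_ranking(report) == ["only"]

    def test_deterministic_tie_break_by_key_order(self):
        report = BenchmarkReport(1, {m: 0 for m in METRICS}, {m: 0 for m in METRICS},
                                 0, 0, mean_importance={"b": 0.5, "a": 0.5, "c": 0.7})
        assert importance_ranking(report) == ["c", "b", "a"]

    def test_importance_mass_follows_the_signal_column(self, rng):
        X = rng.normal(size=(120, 4))
        y = X[:, 2] * 3.0
        cfg = ProtocolConfig(n_splits=1, rf_trees=60, compute_cv=False)
        (run,) = run_protocol(X, y, cfg, col_ids=list("wxyz"))
        assert max(run.importance, key=run.importance.get) == "y"
        assert sum(run.importance.values()) == pytest.approx(1.0)
        # permuting the columns moves the importance mass along
        perm = [3, 2, 1, 0]
        (run2,) = run_protocol(X[:, perm], y, cfg, col_ids=["z", "y", "x", "w"])
        assert max(run2.importance, key=run2.importance.get) == "y"


class TestConfigValidation:
    @pytest.mark.parametrize("kwargs", [{"train_fraction": 0.0}, {"train_fraction": 1.0},
                                        {"n_splits": 0}, {"cv_folds": 1}])
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            ProtocolConfig(**kwargs)
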