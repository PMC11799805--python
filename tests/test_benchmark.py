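"""Benchmark harness: folds, feature extraction, metrics, sweep, aggregation."""

import numpy as np
import pandas as pd
import pytest

from scanpathml import benchmark as b
from scanpathml.synthetic import SimulationConfig, simulate_dataset


def brute_force_auc(y, scores):
    """All-pairs rank AUC with ties counted 1/2 (independent oracle)."""
    pos = scores[y == 1]
    neg = scores[y == 0]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


class TestStratifiedFolds:
    def test_ten_folds_of_five_per_class(self):
        y = np.array(["faculty"] * 55 + ["trainee"] * 55)
        folds = b.stratified_folds(y, 10, 5, seed=0)
        assert len(folds) == 10
        seen = np.concatenate(folds)
        assert len(seen) == len(set(seen)) == 100  # disjoint
        for f in folds:
            assert len(f) == 10
            assert (y[f] == "faculty").sum() == 5
            assert (y[f] == "trainee").sum() == 5

    def test_exhaustive_partition_when_counts_match(self):
        y = np.array([0] * 10 + [1] * 10)
        folds = b.stratified_folds(y, 2, 5, seed=1)
        assert sorted(np.concatenate(folds).tolist()) == list(range(20))

    def test_deterministic_given_seed(self):
        y = np.array([0] * 30 + [1] * 30)
        f1 = b.stratified_folds(y, 3, 4, seed=5)
        f2 = b.stratified_folds(y, 3, 4, seed=5)
        assert all(np.array_equal(a, c) for a, c in zip(f1, f2))

    def test_insufficient_class_members_raises(self):
        y = np.array([0] * 9 + [1] * 50)
        with pytest.raises(b.SizingError, match="0"):
            b.stratified_folds(y, 2, 5, seed=0)


class TestReduceFeatures:
    def test_none_is_identity(self):
        X = np.random.default_rng(0).normal(size=(20, 6))
        tr, te = b.reduce_features(X[:15], X[15:], b.FeatureExtractionSpec())
        assert np.array_equal(tr, X[:15]) and np.array_equal(te, X[15:])

    def test_pca_variance_mode_keeps_minimal_components(self):
        rng = np.random.default_rng(1)
        # component variances ~ (9, 1): one component already explains 90%
        X = np.column_stack([3 * rng.normal(size=400), rng.normal(size=400)])
        spec = b.FeatureExtractionSpec(method="pca", mode="variance",
                                       variance_target=0.50)
        tr, te = b.reduce_features(X[:300], X[300:], spec)
        assert tr.shape[1] == 1 and te.shape[1] == 1

    def test_pca_dims_mode_keeps_exactly_dims(self):
        X = np.random.default_rng(2).normal(size=(30, 10))
        spec = b.FeatureExtractionSpec(method="pca", mode="dims", dims=2)
        tr, te = b.reduce_features(X[:20], X[20:], spec)
        assert tr.shape == (20, 2) and te.shape == (10, 2)

    def test_linear_kernel_kpca_matches_pca_up_to_sign(self):
        X = np.random.default_rng(3).normal(size=(25, 5))
        train, test = X[:18], X[18:]
        p_tr, p_te = b.reduce_features(
            train, test, b.FeatureExtractionSpec(method="pca", dims=2)
        )
        k_tr, k_te = b.reduce_features(
            train, test,
            b.FeatureExtractionSpec(method="kpca", dims=2, kernel="linear"),
        )
        for pc, kc in ((p_tr, k_tr), (p_te, k_te)):
            for j in range(2):
                assert np.allclose(pc[:, j], kc[:, j], atol=1e-8) or np.allclose(
                    pc[:, j], -kc[:, j], atol=1e-8
                )

    def test_kpca_variance_mode_reaches_target(self):
        X = np.random.default_rng(4).normal(size=(40, 8))
        spec = b.FeatureExtractionSpec(method="kpca", mode="variance",
                                       variance_target=0.90)
        tr, _ = b.reduce_features(X[:30], X[30:], spec)
        assert 1 <= tr.shape[1] < 30


class TestComputeMetrics:
    def test_perfect_classifier(self):
        y = np.array([0, 0, 1, 1])
        m = b.compute_metrics(y, np.array([0.1, 0.2, 0.8, 0.9]), y)
        assert (m.auc, m.f1, m.accuracy, m.sensitivity, m.specificity) == (
            1, 1, 1, 1, 1,
        )

    def test_constant_scores_give_half_auc(self):
        y = np.array([0, 1, 0, 1])
        m = b.compute_metrics(y, np.full(4, 0.5), np.array([1, 1, 0, 0]))
        assert m.auc == 0.5

    def test_hand_computed_confusion(self):
        # TP=3 FN=1 TN=4 FP=2
        y_true = np.array([1, 1, 1, 1, 0, 0, 0, 0, 0, 0])
        y_pred = np.array([1, 1, 1, 0, 0, 0, 0, 0, 1, 1])
        m = b.compute_metrics(y_true, y_pred.astype(float), y_pred)
        assert m.sensitivity == pytest.approx(0.75)
        assert m.specificity == pytest.approx(2 / 3)
        assert m.accuracy == pytest.approx(0.7)
        assert m.f1 == pytest.approx(2 * 3 / (2 * 3 + 2 + 1))

    def test_auc_matches_all_pairs_oracle(self):
        rng = np.random.default_rng(8)
        for _ in range(50):
            n = int(rng.integers(4, 30))
            y = np.zeros(n, int)
            y[: max(1, n // 3)] = 1
            rng.shuffle(y)
            if len(np.unique(y)) < 2:
                continue
            scores = np.round(rng.normal(size=n), 1)  # force ties
            m = b.compute_metrics(y, scores, (scores > 0).astype(int))
            assert m.auc == pytest.approx(brute_force_auc(y, scores), abs=1e-12)

    def test_single_class_auc_is_nan(self):
        m = b.compute_metrics(np.ones(4, int), np.ones(4), np.ones(4, int))
        assert np.isnan(m.auc) and m.accuracy == 1.0


class TestFitAndScore:
    def _separable(self, n=40, seed=0):
        """Widely separated classes; test points lie inside the training
        hull of their class so threshold learners cannot miss either."""
        rng = np.random.default_rng(seed)
        train = np.vstack(
            [rng.uniform(-10, -6, (n // 4, 2)), rng.uniform(6, 10, (n // 4, 2))]
        )
        test = np.vstack(
            [rng.uniform(-9, -7, (n // 4, 2)), rng.uniform(7, 9, (n // 4, 2))]
        )
        y_half = np.array([0] * (n // 4) + [1] * (n // 4))
        return train, y_half, test, y_half

    @pytest.mark.parametrize("name", ["lr", "knn", "gp", "xgboost"])
    def test_roster_on_separable_data_is_perfect(self, name):
        Xtr, ytr, Xte, yte = self._separable()
        m = b.fit_and_score(
            b.ClassifierSpec(name), Xtr, ytr, Xte, yte, b.FeatureExtractionSpec()
        )
        assert m.auc == 1.0 and m.accuracy == 1.0

    def test_deterministic_for_fixed_seed(self):
        rng = np.random.default_rng(12)
        X = rng.normal(size=(40, 3))
        y = (X[:, 0] + rng.normal(scale=2, size=40) > 0).astype(int)
        args = (b.ClassifierSpec("knn"), X[:30], y[:30], X[30:], y[30:],
                b.FeatureExtractionSpec())
        assert b.fit_and_score(*args, seed=4) == b.fit_and_score(*args, seed=4)

    def test_single_class_training_split_rejected(self):
        Xtr, ytr, Xte, yte = self._separable()
        with pytest.raises(b.SizingError):
            b.fit_and_score(
                b.ClassifierSpec("lr"), Xtr, np.zeros(len(ytr), int), Xte, yte,
                b.FeatureExtractionSpec(),
            )


@pytest.fixture(scope="module")
def small_records():
    """A quick real sweep on a small synthetic dataset (lr only)."""
    ds = simulate_dataset(
        SimulationConfig(n_participants_per_class=1, trials_per_participant=20,
                         seed=5, separation=0.8)
    )
    sweep = b.SweepConfig(
        grid_sizes=(5,),
        temporal_groups=(3,),
        classifiers=(b.ClassifierSpec("lr"),),
        k_folds=4,
        per_class_holdout=4,
        seeds=(0,),
    )
    return b.run_sweep(ds, sweep)


class TestRunSweep:
    def test_one_record_per_fold_and_cell(self, small_records):
        rec = small_records
        # (encoded 1 grid x 1 t + traditional) x 1 clf x 1 seed x 4 folds
        assert len(rec) == 8
        assert set(rec["data_type"]) == {"encoded", "traditional"}
        assert set(rec.loc[rec.data_type == "traditional", "grid"]) == {0}
        assert rec[b.METRIC_COLUMNS].stack().between(0, 1).all()

    def test_keys_unique(self, small_records):
        assert not small_records.duplicated(subset=b.KEY_COLUMNS).any()


class TestAggregation:
    def _table(self):
        rows = [
            dict(device="d", classifier="lr", data_type="encoded", fe="none",
                 grid=5, t=3, seed=0, fold=0, auc=0.8, f1=0.8, accuracy=0.8,
                 sensitivity=0.8, specificity=0.8),
            dict(device="d", classifier="lr", data_type="encoded", fe="none",
                 grid=5, t=3, seed=0, fold=1, auc=0.6, f1=0.6, accuracy=0.6,
                 sensitivity=0.6, specificity=0.6),
        ]
        return pd.DataFrame(rows)

    def test_mean_over_shared_key(self):
        out = b.aggregate(self._table(), ["classifier"])
        assert out.loc[0, "auc_mean"] == pytest.approx(0.7)

    def test_singleton_variance_and_full_key_identity(self):
        tbl = self._table()
        full = b.aggregate(tbl, b.KEY_COLUMNS)
        assert len(full) == 2 and (full["auc_var"].isna() | (full["auc_var"] == 0)).all()
        assert full["auc_mean"].tolist() == tbl["auc"].tolist()

    def test_permutation_invariant(self):
        tbl = self._table()
        shuffled = tbl.iloc[::-1].reset_index(drop=True)
        a = b.aggregate(tbl, ["classifier", "data_type"])
        c = b.aggregate(shuffled, ["classifier", "data_type"])
        pd.testing.assert_frame_equal(a, c)


def _records_grid(auc_by_cfg, classifier="lr", data_type="encoded"):
    rows = []
    for (g, t, fe), auc in auc_by_cfg.items():
        rows.append(
            dict(device="d", classifier=classifier, data_type=data_type, fe=fe,
                 grid=g, t=t, seed=0, fold=0, auc=auc, f1=auc, accuracy=auc,
                 sensitivity=auc, specificity=auc)
        )
    return pd.DataFrame(rows)


class TestSelection:
    def test_argmax_config(self):
        tbl = _records_grid(
            {(5, 3, "none"): 0.9, (5, 10, "none"): 0.8, (10, 3, "none"): 0.8}
        )
        assert b.select_best_config(tbl, "lr") == (5, 3, "none")

    def test_tie_breaks_prefer_simpler(self):
        cfgs = {
            (g, t, fe): 0.8
            for g in (5, 10)
            for t in (3, 10)
            for fe in ("none", "pca_2d")
        }
        assert b.select_best_config(_records_grid(cfgs), "lr") == (5, 3, "none")

    def test_missing_classifier_raises(self):
        with pytest.raises(KeyError):
            b.select_best_config(_records_grid({(5, 3, "none"): 0.9}), "gp")


class TestCompareGain:
    def test_gain_in_points(self):
        enc = _records_grid({(5, 3, "none"): 0.9})
        trad = _records_grid({(0, 0, "none"): 0.8}, data_type="traditional")
        gains = b.compare_gain(pd.concat([enc, trad], ignore_index=True))
        auc_row = gains[gains.metric == "auc"].iloc[0]
        assert auc_row["gain_points"] == pytest.approx(10.0)
        assert len(gains) == 5  # one device x five metrics

    def test_identical_tables_zero_gain(self):
        enc = _records_grid({(5, 3, "none"): 0.75})
        trad = _records_grid({(0, 0, "none"): 0.75}, data_type="traditional")
        gains = b.compare_gain(pd.concat([enc, trad], ignore_index=True))
        assert np.allclose(gains["gain_points"], 0.0)

    def test_missing_data_type_raises(self):
        with pytest.raises(b.ComparisonError):
            b.compare_gain(_records_grid({(5, 3, "none"): 0.9}))
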