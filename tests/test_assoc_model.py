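import numpy as np
import pytest

from hetmda import assoc_model
from hetmda.assoc_model import (DegenerateDataError, FeatureTable,
                                InsufficientNegativesError, build_pair_dataset,
                                compute_metrics, cross_validate, evaluate,
                                kfold_split, positive_scores, rank_candidates,
                                train_classifier)


def small_features(n_mirna=3, n_disease=3, dim=4, seed=0) -> FeatureTable:
    rng = np.random.default_rng(seed)
    return FeatureTable(
        mirna_ids=[f"m{i}" for i in range(n_mirna)],
        disease_ids=[f"d{i}" for i in range(n_disease)],
        mirna_attr=rng.random((n_mirna, dim)),
        mirna_beh=rng.random((n_mirna, dim)),
        disease_attr=rng.random((n_disease, dim)),
        disease_beh=rng.random((n_disease, dim)),
    )


class TestFeatureTable:
    def test_fused_length(self):
        ft = small_features()
        assert len(ft.node_vector("m0", "miRNA", "both")) == 8
        assert len(ft.node_vector("m0", "miRNA", "attribute")) == 4
        assert len(ft.pair_vector("m0", "d0", "both")) == 16

    def test_bad_mode(self):
        with pytest.raises(ValueError):
            small_features().node_vector("m0", "miRNA", "fused")

    def test_round_trip(self, tmp_path):
        ft = small_features()
        ft.save(tmp_path / "f")
        loaded = FeatureTable.load(tmp_path / "f")
        assert loaded.mirna_ids == ft.mirna_ids
        np.testing.assert_array_equal(loaded.disease_beh, ft.disease_beh)


class TestBuildPairDataset:
    def test_balanced_and_disjoint(self):
        ft = small_features()
        pos = [("m0", "d0"), ("m0", "d1"), ("m1", "d0"), ("m2", "d2")]
        ds = build_pair_dataset(pos, ft, seed=0)
        assert len(ds.pairs) == 8
        assert ds.y.sum() == 4
        assert len(set(ds.pairs)) == 8
        negs = set(ds.pairs[4:])
        assert negs.isdisjoint(set(pos))

    def test_same_seed_identical(self):
        ft = small_features()
        pos = [("m0", "d0"), ("m1", "d1")]
        a = build_pair_dataset(pos, ft, seed=5)
        b = build_pair_dataset(pos, ft, seed=5)
        assert a.pairs == b.pairs
        np.testing.assert_array_equal(a.X, b.X)

    def test_insufficient_negatives(self):
        ft = small_features(n_mirna=2, n_disease=2)
        pos = [("m0", "d0"), ("m0", "d1"), ("m1", "d0")]
        with pytest.raises(InsufficientNegativesError):
            build_pair_dataset(pos, ft)

    def test_missing_features_rejected(self):
        with pytest.raises(KeyError):
            build_pair_dataset([("mX", "d0")], small_features())


class TestKFold:
    def test_equal_split(self):
        ft = small_features(n_mirna=20, n_disease=20)
        pos = [(f"m{i}", f"d{i}") for i in range(20)] + \
              [(f"m{i}", f"d{(i+1) % 20}") for i in range(20)] + \
              [(f"m{i}", f"d{(i+2) % 20}") for i in range(10)]
        ds = build_pair_dataset(pos, ft, seed=0)  # 100 samples
        folds = kfold_split(ds, k=5, seed=0)
        assert sorted(np.bincount(folds)) == [20] * 5

    def test_remainder_rule(self):
        rng = np.random.default_rng(0)
        ds = assoc_model.PairDataset(pairs=[("m", "d")] * 101,
                                     X=rng.random((101, 2)),
                                     y=np.r_[np.ones(51), np.zeros(50)],
                                     mode="both", seed=0)
        folds = kfold_split(ds, k=5, seed=0)
        assert sorted(np.bincount(folds), reverse=True) == [21, 20, 20, 20, 20]

    def test_partition(self):
        ft = small_features(n_mirna=10, n_disease=10)
        pos = [(f"m{i}", f"d{i}") for i in range(10)]
        ds = build_pair_dataset(pos, ft, seed=0)
        folds = kfold_split(ds, k=4, seed=1)
        assert len(folds) == len(ds.y)
        assert set(folds) == {0, 1, 2, 3}

    def test_k_too_small(self):
        ft = small_features()
        ds = build_pair_dataset([("m0", "d0")], ft)
        with pytest.raises(ValueError):
            kfold_split(ds, k=1)


def separable_data(n=60, seed=0):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, 4))
    y = (X[:, 0] > 0).astype(int)
    X[:, 0] += y * 5.0
    return X, y


class TestTrainClassifier:
    def test_separable_training_auc_one(self):
        X, y = separable_data()
        model = train_classifier("RandomForest", X, y, seed=0)
        metrics = evaluate(model, X, y)
        assert metrics["AUC"] == 1.0

    def test_same_seed_identical_predictions(self):
        X, y = separable_data()
        s1 = positive_scores(train_classifier("RandomForest", X, y, seed=2), X)
        s2 = positive_scores(train_classifier("RandomForest", X, y, seed=2), X)
        np.testing.assert_array_equal(s1, s2)

    def test_single_class_rejected(self):
        X, _ = separable_data()
        with pytest.raises(DegenerateDataError):
            train_classifier("RandomForest", X, np.ones(len(X)))

    def test_unknown_kind(self):
        X, y = separable_data()
        with pytest.raises(ValueError):
            train_classifier("SVM", X, y)

    @pytest.mark.parametrize("kind", assoc_model.CLASSIFIERS)
    def test_all_kinds_fit_and_score(self, kind):
        X, y = separable_data()
        model = train_classifier(kind, X, y, seed=0)
        scores = positive_scores(model, X)
        assert scores.shape == (len(y),)
        assert (scores >= 0).all() and (scores <= 1).all()

    def test_permuted_labels_give_chance_auc(self):
        rng = np.random.default_rng(42)
        X = rng.normal(size=(200, 6))
        y = rng.permutation(np.r_[np.ones(100), np.zeros(100)]).astype(int)
        aucs = []
        for fold in range(5):
            test = np.arange(200) % 5 == fold
            model = train_classifier("RandomForest", X[~test], y[~test], seed=0)
            aucs.append(evaluate(model, X[test], y[test])["AUC"])
        assert abs(float(np.mean(aucs)) - 0.5) < 0.1


class TestMetrics:
    def test_worked_confusion_matrix(self):
        # TP=8 TN=9 FP=1 FN=2 at threshold 0.5
        y = np.array([1] * 10 + [0] * 10)
        scores = np.r_[np.full(8, 0.9), np.full(2, 0.1),   # 8 TP, 2 FN
                       np.full(1, 0.9), np.full(9, 0.1)]   # 1 FP, 9 TN
        m = compute_metrics(scores, y)
        assert (m["TP"], m["TN"], m["FP"], m["FN"]) == (8, 9, 1, 2)
        assert m["Acc"] == pytest.approx(0.85)
        assert m["Sen"] == pytest.approx(0.8)
        assert m["Spec"] == pytest.approx(0.9)
        assert m["Prec"] == pytest.approx(8 / 9)
        assert m["MCC"] == pytest.approx(70 / np.sqrt(9900), abs=1e-4)

    def test_perfect_ranking(self):
        y = np.array([0, 0, 1, 1])
        scores = np.array([0.1, 0.2, 0.8, 0.9])
        m = compute_metrics(scores, y)
        assert m["AUC"] == 1.0
        assert m["AUPR"] == 1.0

    def test_constant_scores_auc_half(self):
        y = np.array([0, 1, 0, 1])
        m = compute_metrics(np.full(4, 0.7), y)
        assert m["AUC"] == 0.5

    def test_undefined_metric_is_nan_with_warning(self):
        y = np.zeros(4, dtype=int)
        with pytest.warns(UserWarning):
            m = compute_metrics(np.full(4, 0.1), y)
        assert np.isnan(m["Sen"])
        assert np.isnan(m["AUC"])

    def test_auc_invariant_under_monotone_transform(self, rng):
        for _ in range(20):
            y = rng.integers(0, 2, size=40)
            if len(np.unique(y)) < 2:
                continue
            s = rng.random(40)
            a1 = compute_metrics(s, y)["AUC"]
            a2 = compute_metrics(np.exp(3 * s) + 7, y)["AUC"]
            assert a1 == pytest.approx(a2, abs=1e-12)


class TestCrossValidate:
    def make_dataset(self, n=100, seed=0):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(n, 4))
        y = (X[:, 0] + 0.5 * rng.normal(size=n) > 0).astype(int)
        return assoc_model.PairDataset(pairs=[("m", "d")] * n, X=X, y=y,
                                       mode="both", seed=seed)

    def test_mean_equals_arithmetic_mean(self):
        ds = self.make_dataset()
        report = cross_validate(ds, seed=0)
        for metric in ("AUC", "Acc"):
            folds = [f[metric] for f in report.per_fold]
            assert report.mean[metric] == pytest.approx(np.mean(folds), abs=1e-12)

    def test_identical_folds_zero_std(self):
        report = assoc_model.MetricsReport(
            per_fold=[{m: 0.8 for m in assoc_model.SCALAR_METRICS}] * 5,
            classifier="RandomForest", mode="both", seed=0)
        assert all(v == 0.0 for v in report.std.values())

    def test_report_serializes(self, tmp_path):
        ds = self.make_dataset()
        report = cross_validate(ds, seed=0)
        report.to_json(tmp_path / "r.json")
        import json
        data = json.loads((tmp_path / "r.json").read_text())
        assert set(data["mean"]) == set(assoc_model.SCALAR_METRICS)
        assert len(data["folds"]) == 5


class TestRankCandidates:
    def setup_model(self):
        ft = small_features(n_mirna=5, n_disease=2, seed=1)
        pos = [("m0", "d0"), ("m1", "d0"), ("m0", "d1"), ("m2", "d1")]
        ds = build_pair_dataset(pos, ft, seed=0)
        model = train_classifier("RandomForest", ds.X, ds.y, seed=0)
        return ft, pos, model

    def test_training_pairs_excluded(self):
        ft, pos, model = self.setup_model()
        ranked = rank_candidates("d0", model, ft, pos)
        names = [m for m, _ in ranked]
        assert "m0" not in names and "m1" not in names
        assert set(names) == {"m2", "m3", "m4"}

    def test_all_in_training_gives_empty(self):
        ft, pos, model = self.setup_model()
        all_pos = [(f"m{i}", "d0") for i in range(5)]
        assert rank_candidates("d0", model, ft, all_pos) == []

    def test_sorted_desc_ties_by_id(self):
        ft, pos, model = self.setup_model()
        ranked = rank_candidates("d1", model, ft, pos)
        for (m1, s1), (m2, s2) in zip(ranked, ranked[1:]):
            assert s1 > s2 or (s1 == s2 and m1 < m2)

    def test_unknown_disease(self):
        ft, pos, model = self.setup_model()
        with pytest.raises(KeyError):
            rank_candidates("dX", model, ft, pos)
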