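import numpy as np
import pytest
from sklearn.model_selection import ParameterGrid

from hybridfs import (
    Dataset,
    EvaluatorSpec,
    OverallRankTable,
    RankTable,
    accuracy_from_counts,
    build_ort,
    cv_evaluate,
    make_classifier,
    sequential_forward_select,
)


def ort_for(names):
    """ORT whose order is exactly `names` (strictly increasing rank sums)."""
    ranks = np.array([[i + 1, i + 1, i + 1] for i in range(len(names))])
    return build_ort(RankTable(list(names), ranks))


@pytest.fixture
def separable_dataset():
    """n=40 two-class set where 'signal' separates perfectly and the rest
    is pure noise."""
    rng = np.random.default_rng(0)
    y = np.array(["a"] * 20 + ["b"] * 20)
    signal = np.where(y == "a", 0.1, 0.9) + rng.normal(0, 0.01, 40)
    noise = rng.random((40, 3))
    return Dataset(
        np.column_stack([signal, noise]),
        ["signal", "n1", "n2", "n3"],
        y,
    )


class TestAccuracyFromCounts:
    @pytest.mark.parametrize(
        "counts,expected",
        [((1, 1, 0, 0), 1.0), ((0, 0, 1, 1), 0.0), ((45, 25, 2, 0), 70 / 72)],
    )
    def test_examples(self, counts, expected):
        assert accuracy_from_counts(*counts) == pytest.approx(expected)

    def test_zero_total_rejected(self):
        with pytest.raises(ValueError):
            accuracy_from_counts(0, 0, 0, 0)


class TestMakeClassifier:
    def test_knn_grid_cardinality(self):
        spec = EvaluatorSpec(classifier_name="knn", hyper_grid={"n_neighbors": [1, 3, 5]})
        assert len(list(ParameterGrid(spec.grid))) == 3

    def test_svm_smoke_fit(self):
        rng = np.random.default_rng(0)
        model = make_classifier(EvaluatorSpec(classifier_name="svm"))
        X = rng.random((10, 3))
        y = np.array(["a", "b"] * 5)
        model.fit(X, y)
        assert len(model.predict(X)) == 10

    def test_unknown_name_rejected(self):
        with pytest.raises(ValueError, match="classifier_name"):
            EvaluatorSpec(classifier_name="mlp")

    def test_custom_requires_model(self):
        with pytest.raises(ValueError, match="custom_model"):
            EvaluatorSpec(classifier_name="custom")


class TestCvEvaluate:
    def test_separable_feature_perfect_accuracy(self, separable_dataset):
        spec = EvaluatorSpec(classifier_name="knn", cv_folds=5, seed=0)
        result = cv_evaluate(separable_dataset, ["signal"], spec)
        assert result.accuracy == pytest.approx(1.0)

    def test_accuracy_is_mean_of_folds(self, separable_dataset):
        spec = EvaluatorSpec(classifier_name="dt", cv_folds=5, seed=1)
        result = cv_evaluate(separable_dataset, ["signal", "n1"], spec)
        assert result.accuracy == pytest.approx(np.mean(result.per_fold_accuracy))
        assert len(result.per_fold_accuracy) == 5

    def test_deterministic_given_seed(self, separable_dataset):
        spec = EvaluatorSpec(classifier_name="rf", cv_folds=4, seed=3,
                             hyper_grid={"n_estimators": [10, 20]})
        a = cv_evaluate(separable_dataset, ["n1", "n2"], spec)
        b = cv_evaluate(separable_dataset, ["n1", "n2"], spec)
        assert a.accuracy == b.accuracy
        assert a.per_fold_accuracy == b.per_fold_accuracy

    def test_permuted_labels_within_null_band(self):
        """A single CV evaluation of a noise feature on balanced two-class
        n=100 stays inside the ~3-sigma binomial band."""
        rng = np.random.default_rng(5)
        values = rng.random((100, 2))
        labels = rng.permutation(np.array(["a", "b"] * 50))
        data = Dataset(values, ["g1", "g2"], labels)
        spec = EvaluatorSpec(classifier_name="knn", cv_folds=10, seed=5)
        result = cv_evaluate(data, ["g1"], spec)
        assert 0.35 <= result.accuracy <= 0.65

    def test_constant_feature_near_chance(self):
        y = np.array(["a", "b"] * 25)
        values = np.column_stack([np.zeros(50), np.arange(50.0)])
        data = Dataset(values, ["flat", "other"], y)
        spec = EvaluatorSpec(classifier_name="dt", cv_folds=5, seed=2)
        result = cv_evaluate(data, ["flat"], spec)
        assert 0.3 <= result.accuracy <= 0.7

    def test_unknown_feature_rejected(self, separable_dataset):
        spec = EvaluatorSpec(classifier_name="knn")
        with pytest.raises(KeyError):
            cv_evaluate(separable_dataset, ["absent"], spec)
        with pytest.raises(ValueError, match="non-empty"):
            cv_evaluate(separable_dataset, [], spec)


class TestSequentialForwardSelect:
    def test_hand_trace_tie_excluded(self):
        """{f1}=0.8, {f1,f2}=0.8, {f1,f3}=0.9: the tie on f2 must exclude it."""
        table = {("f1",): 0.8, ("f1", "f2"): 0.8, ("f1", "f3"): 0.9}
        result = sequential_forward_select(
            ort_for(["f1", "f2", "f3"]),
            None,
            EvaluatorSpec(classifier_name="knn", seed=0),
            evaluate=lambda s: table[tuple(s)],
        )
        assert result.selected_features == ["f1", "f3"]
        assert result.best_accuracy == pytest.approx(0.9)
        kept = {s.feature: s.kept for s in result.trajectory}
        assert kept == {"f1": True, "f2": False, "f3": True}

    def test_no_improvement_keeps_only_first(self):
        result = sequential_forward_select(
            ort_for(["f1", "f2", "f3"]),
            None,
            EvaluatorSpec(classifier_name="knn", seed=0),
            evaluate=lambda s: 0.7,
        )
        assert result.selected_features == ["f1"]
        assert result.best_accuracy == pytest.approx(0.7)

    def test_monotone_evaluator_keeps_all(self):
        names = ["f1", "f2", "f3", "f4"]
        result = sequential_forward_select(
            ort_for(names),
            None,
            EvaluatorSpec(classifier_name="knn", seed=0),
            evaluate=lambda s: len(s) / 10,
        )
        assert result.selected_features == names
        accuracies = [s.accuracy for s in result.trajectory]
        assert all(b > a for a, b in zip(accuracies, accuracies[1:]))

    @pytest.mark.parametrize("seed", range(5))
    def test_planted_set_oracle_recovered_exactly(self, seed):
        """With acc(S) = |S ∩ T|/|T| and T heading the ORT, the greedy loop
        must return exactly T."""
        rng = np.random.default_rng(seed)
        m = int(rng.integers(3, 11))
        names = [f"f{i}" for i in range(m)]
        true_size = int(rng.integers(1, m))
        true_set = set(names[:true_size])
        result = sequential_forward_select(
            ort_for(names),
            None,
            EvaluatorSpec(classifier_name="knn", seed=seed),
            evaluate=lambda s: len(set(s) & true_set) / len(true_set),
        )
        assert set(result.selected_features) == true_set
        assert result.best_accuracy == pytest.approx(1.0)

    def test_trajectory_covers_every_feature(self):
        names = [f"f{i}" for i in range(6)]
        result = sequential_forward_select(
            ort_for(names),
            None,
            EvaluatorSpec(classifier_name="knn", seed=0),
            evaluate=lambda s: 0.5 + 0.01 * len(s),
        )
        assert [s.feature for s in result.trajectory] == names

    def test_max_features_cap(self):
        names = [f"f{i}" for i in range(5)]
        result = sequential_forward_select(
            ort_for(names),
            None,
            EvaluatorSpec(classifier_name="knn", seed=0),
            evaluate=lambda s: 0.5 + 0.05 * len(s),
            max_features=2,
        )
        assert len(result.selected_features) == 2
        assert len(result.trajectory) == 5

    def test_best_accuracy_consistent_with_reevaluation(self, separable_dataset):
        spec = EvaluatorSpec(classifier_name="knn", cv_folds=5, seed=0)
        ort = ort_for(["signal", "n1", "n2", "n3"])
        result = sequential_forward_select(ort, separable_dataset, spec)
        again = cv_evaluate(separable_dataset, result.selected_features, spec)
        assert result.best_accuracy == pytest.approx(again.accuracy)
        assert result.best_accuracy >= result.trajectory[0].accuracy

    def test_custom_estimator_runs_deterministically(self, separable_dataset):
        from sklearn.dummy import DummyClassifier

        spec = EvaluatorSpec(
            classifier_name="custom",
            custom_model=DummyClassifier(strategy="most_frequent"),
            cv_folds=4,
            seed=1,
        )
        ort = ort_for(["signal", "n1"])
        a = sequential_forward_select(ort, separable_dataset, spec)
        b = sequential_forward_select(ort, separable_dataset, spec)
        assert a.to_dict() == b.to_dict()

    def test_result_serialization(self, tmp_path):
        result = sequential_forward_select(
            ort_for(["f1", "f2"]),
            None,
            EvaluatorSpec(classifier_name="knn", seed=0),
            evaluate=lambda s: 0.5 + 0.1 * len(s),
        )
        path = tmp_path / "result.json"
        result.to_json(str(path))
        import json

        loaded = json.loads(path.read_text())
        assert loaded["selected_features"] == ["f1", "f2"]
        assert loaded["best_accuracy"] == pytest.approx(0.7)
        assert len(loaded["trajectory"]) == 2
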