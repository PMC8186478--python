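"""Classifier back-ends, rejection, cross-validation and sensitivity."""

import numpy as np
import pandas as pd
import pytest

from cycleclass import (
    METHODS,
    UNKNOWN_LABEL,
    ClassifierModel,
    cross_validate,
    dropout_sensitivity,
    load_model,
    predict_with_rejection,
    save_model,
    train_classifier,
)
from cycleclass.errors import ContractError, ParameterError
from conftest import make_norm


class _FixedProba:
    """Stub estimator returning a fixed probability matrix."""

    def __init__(self, proba, classes):
        self._proba = np.asarray(proba, dtype=float)
        self.classes_ = np.asarray(classes)

    def predict_proba(self, X):
        return self._proba[: X.shape[0]]


def _stub_model(proba, classes, n_features=3):
    return ClassifierModel(
        method="RF",
        feature_genes=[f"f{i}" for i in range(n_features)],
        feature_means=np.zeros(n_features),
        feature_sds=np.ones(n_features),
        class_labels=list(classes),
        estimator=_FixedProba(proba, classes),
        rejection_cutoff=0.7,
    )


def _aligned(n_cells, genes):
    return make_norm(np.zeros((len(genes), n_cells)), gene_ids=list(genes))


class TestRejection:
    def test_certain_cell_assigned_at_any_cutoff(self):
        model = _stub_model([[1.0, 0.0]], ["a", "b"])
        for theta in (0.0, 0.5, 1.0):
            pred = predict_with_rejection(model, _aligned(1, model.feature_genes), theta)
            assert pred.labels[0] == "a"

    def test_cutoff_is_inclusive(self):
        model = _stub_model([[0.69, 0.31], [0.70, 0.30]], ["a", "b"])
        pred = predict_with_rejection(model, _aligned(2, model.feature_genes), 0.7)
        assert pred.labels[0] == UNKNOWN_LABEL  # 0.69 < 0.7
        assert pred.labels[1] == "a"  # 0.70 >= 0.7, inclusive

    def test_zero_cutoff_disables_rejection(self):
        model = _stub_model([[0.4, 0.6]], ["a", "b"])
        pred = predict_with_rejection(model, _aligned(1, model.feature_genes), 0.0)
        assert pred.labels[0] == "b"

    def test_default_cutoffs_by_method(self, separable_dataset):
        norm, labels = separable_dataset
        svm = train_classifier(norm, labels, method="SVMrej", seed=0)
        rf = train_classifier(norm, labels, method="RF", seed=0)
        assert svm.rejection_cutoff == 0.7
        assert rf.rejection_cutoff == 0.0

    def test_monotonicity_lower_cutoff_never_loses_cells(self, small_norm, small_sim, small_hvg):
        model = train_classifier(
            small_norm, small_sim.true_labels, method="RF",
            feature_genes=small_hvg, seed=0,
        )
        aligned = model.align(small_norm)
        assigned = []
        for theta in (0.9, 0.7, 0.5, 0.3, 0.0):
            pred = predict_with_rejection(model, aligned, theta)
            assigned.append(int(np.sum(pred.labels != UNKNOWN_LABEL)))
        assert all(a <= b for a, b in zip(assigned, assigned[1:]))

    def test_unaligned_matrix_is_contract_error(self, separable_dataset):
        norm, labels = separable_dataset
        model = train_classifier(norm, labels, method="RF", seed=0)
        wrong = make_norm(np.zeros((2, 3)), gene_ids=["x", "y"])
        with pytest.raises(ContractError):
            predict_with_rejection(model, wrong)


class TestTraining:
    @pytest.mark.parametrize("method", METHODS)
    def test_separable_classes_perfect_training_accuracy(
        self, separable_dataset, method
    ):
        norm, labels = separable_dataset
        model = train_classifier(norm, labels, method=method, seed=0)
        pred = predict_with_rejection(model, model.align(norm), 0.0)
        assert np.mean(pred.labels == labels) == 1.0

    def test_same_seed_identical_predictions(self, small_norm, small_sim, small_hvg):
        preds = []
        for _ in range(2):
            model = train_classifier(
                small_norm, small_sim.true_labels, method="NN",
                feature_genes=small_hvg, seed=123,
            )
            pred = predict_with_rejection(model, model.align(small_norm), 0.0)
            preds.append(pred.probabilities.to_numpy())
        np.testing.assert_array_equal(preds[0], preds[1])

    def test_probabilities_sum_to_one(self, small_norm, small_sim, small_hvg):
        model = train_classifier(
            small_norm, small_sim.true_labels, method="NN",
            feature_genes=small_hvg, seed=3,
        )
        pred = predict_with_rejection(model, model.align(small_norm), 0.0)
        sums = pred.probabilities.sum(axis=1).to_numpy()
        np.testing.assert_allclose(sums, 1.0, atol=1e-6)

    def test_tiny_class_rejected(self):
        norm = make_norm(np.random.default_rng(0).normal(size=(5, 10)))
        labels = np.array(["a"] * 9 + ["b"])
        with pytest.raises(ParameterError, match="b"):
            train_classifier(norm, labels, method="RF")

    def test_missing_feature_gene_rejected(self, separable_dataset):
        norm, labels = separable_dataset
        with pytest.raises(ParameterError):
            train_classifier(norm, labels, feature_genes=["nope"], method="RF")

    def test_save_load_round_trip(self, separable_dataset, tmp_path):
        norm, labels = separable_dataset
        model = train_classifier(norm, labels, method="RF", seed=0)
        save_model(model, tmp_path / "model.pkl")
        back = load_model(tmp_path / "model.pkl")
        a = predict_with_rejection(model, model.align(norm), 0.0)
        b = predict_with_rejection(back, back.align(norm), 0.0)
        np.testing.assert_array_equal(a.labels, b.labels)


class TestCrossValidate:
    def test_separable_data_zero_error_all_f1_one(self, separable_dataset):
        norm, labels = separable_dataset
        report = cross_validate(
            norm, labels, method="RF", n_iter=3, holdout_size=40, seed=1
        )
        assert report.errors["error_rate"].eq(0).all()
        assert report.f1["f1"].eq(1.0).all()
        # long table: n_iter x n_classes rows
        assert len(report.f1) == 3 * 2

    def test_summary_has_median_and_iqr(self, separable_dataset):
        norm, labels = separable_dataset
        report = cross_validate(
            norm, labels, method="RF", n_iter=2, holdout_size=40, seed=1
        )
        summary = report.summary()
        assert set(summary.columns) == {"class", "median_f1", "iqr_f1"}
        assert summary["median_f1"].between(0, 1).all()

    def test_holdout_too_large_rejected(self, separable_dataset):
        norm, labels = separable_dataset
        with pytest.raises(ParameterError):
            cross_validate(norm, labels, holdout_size=norm.n_cells)

    def test_reproducible_fold_sequence(self, separable_dataset):
        norm, labels = separable_dataset
        r1 = cross_validate(norm, labels, method="RF", n_iter=2, holdout_size=30, seed=9)
        r2 = cross_validate(norm, labels, method="RF", n_iter=2, holdout_size=30, seed=9)
        pd.testing.assert_frame_equal(r1.errors, r2.errors)

    def test_permuted_labels_give_chance_accuracy(self, small_norm, small_sim, small_hvg):
        rng = np.random.default_rng(5)
        permuted = rng.permutation(small_sim.true_labels.labels)
        report = cross_validate(
            small_norm, permuted, method="RF", n_iter=3, holdout_size=150,
            seed=2, feature_genes=small_hvg,
        )
        # independent predictions: accuracy lies between the smallest and
        # largest class frequency (sum_i p_i q_i), whatever the bias
        _, counts = np.unique(permuted.astype(str), return_counts=True)
        freqs = counts / counts.sum()
        acc = 1 - report.mean_error
        se = np.sqrt(freqs.max() * (1 - freqs.max()) / 150)
        assert freqs.min() - 3 * se <= acc <= freqs.max() + 3 * se


class TestDropoutSensitivity:
    def test_zero_fraction_matches_baseline(self, separable_dataset):
        norm, labels = separable_dataset
        curve = dropout_sensitivity(
            norm, labels, method="RF", fraction_grid=(0.0,), repeats=1,
            seed=4, n_iter=2, holdout_size=40,
        )
        baseline = cross_validate(
            norm, labels, method="RF", n_iter=2, holdout_size=40, seed=4
        )
        assert curve.samples["error_rate"].iloc[0] == pytest.approx(
            baseline.mean_error
        )

    def test_full_removal_falls_back_to_majority(self, small_norm, small_sim):
        y = small_sim.true_labels.labels
        curve = dropout_sensitivity(
            small_norm, y, method="RF", fraction_grid=(1.0,), repeats=1,
            seed=0, n_iter=2, holdout_size=100,
        )
        err = curve.samples["error_rate"].iloc[0]
        # majority class ("G1") frequency ~ its simulated proportion
        _, counts = np.unique(y.astype(str), return_counts=True)
        majority = counts.max() / counts.sum()
        assert err == pytest.approx(1 - majority, abs=0.1)

    def test_default_grid_includes_forty_percent(self):
        import inspect

        sig = inspect.signature(dropout_sensitivity)
        assert 0.4 in sig.parameters["fraction_grid"].default

    def test_invalid_fraction_rejected(self, separable_dataset):
        norm, labels = separable_dataset
        with pytest.raises(ParameterError):
            dropout_sensitivity(norm, labels, fraction_grid=(1.5,))
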