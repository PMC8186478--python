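"""Training, rejection-based prediction and stress-testing of the
cell-cycle classifier.

Four interchangeable back-ends are supported, mirroring the methods
commonly benchmarked for scRNA-seq annotation:

* ``SVMrej`` -- linear-kernel SVM with probability calibration and a
  rejection option (cells whose top class probability falls below the
  cutoff are labeled ``Unknown``; default cutoff 0.7, inclusive).
* ``RF`` -- random forest, 100 trees, class-frequency weighted.
* ``KNN`` -- query cells are projected into the reference's top-30
  principal-component space and classified by majority vote of the 10
  nearest reference cells (the scRNA-seq "ingest" idea as a contract).
* ``NN`` -- a fully connected network with 100/50/25 hidden units,
  softmax output and cross-entropy loss (the ACTINN architecture),
  trained with Adam, mini-batches of 128, up to 50 epochs.

Features are standardized with the training mean/SD stored on the
model; query genes absent at prediction time contribute z = 0 (the
training mean), which keeps linear scores unbiased under gene dropout.
Cross-validation is repeated random subsampling: each iteration holds
out a uniform random set of cells (default 1,000), trains on the rest
and scores the holdout -- 100 iterations by default.  The sensitivity
analysis reruns this while deleting a growing random fraction of the
feature genes.
"""

from __future__ import annotations

import logging
import pickle
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA
from sklearn.dummy import DummyClassifier
from sklearn.ensemble import RandomForestClassifier
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.svm import SVC

from .errors import ContractError, ParameterError
from .preprocess import NormalizedMatrix, align_genes, select_hvg
from .stats import f1_score

logger = logging.getLogger("cycleclass")

UNKNOWN_LABEL = "Unknown"
MODEL_FORMAT_VERSION = 1
METHODS = ("SVMrej", "RF", "KNN", "NN")
DEFAULT_REJECTION = {"SVMrej": 0.7, "RF": 0.0, "KNN": 0.0, "NN": 0.0}

__all__ = [
    "METHODS",
    "UNKNOWN_LABEL",
    "PhaseLabeling",
    "ClassifierModel",
    "CVReport",
    "SensitivityCurve",
    "train_classifier",
    "predict_with_rejection",
    "cross_validate",
    "dropout_sensitivity",
    "save_model",
    "load_model",
]


@dataclass
class PhaseLabeling:
    """Per-cell categorical phase assignment, optionally with probabilities.

    ``labels`` holds one class name (or ``Unknown``) per cell;
    ``probabilities`` is a cells x classes DataFrame when produced by a
    classifier, or ``None`` for ground-truth labelings.
    """

    labels: np.ndarray
    cell_ids: list[str] | None = None
    probabilities: pd.DataFrame | None = None
    rejection_cutoff: float | None = None

    def __post_init__(self):
        self.labels = np.asarray(self.labels, dtype=object)
        if self.cell_ids is not None and len(self.cell_ids) != len(self.labels):
            raise ParameterError("cell_ids length does not match labels")

    def __len__(self) -> int:
        return len(self.labels)

    def value_counts(self) -> pd.Series:
        return pd.Series(self.labels).value_counts()


class _PCAKNNClassifier:
    """KNN in the reference's top principal-component space."""

    def __init__(self, n_components=30, n_neighbors=10, random_state=0):
        self.n_components = n_components
        self.n_neighbors = n_neighbors
        self.random_state = random_state

    def fit(self, X, y):
        n_comp = min(self.n_components, X.shape[1], X.shape[0] - 1)
        n_comp = max(n_comp, 1)
        self._pca = PCA(n_components=n_comp, svd_solver="full")
        Z = self._pca.fit_transform(X)
        k = min(self.n_neighbors, X.shape[0])
        self._knn = KNeighborsClassifier(n_neighbors=k)
        self._knn.fit(Z, y)
        self.classes_ = self._knn.classes_
        return self

    def predict_proba(self, X):
        return self._knn.predict_proba(self._pca.transform(X))


def _make_estimator(method: str, hyperparams: dict, seed: int):
    hp = dict(hyperparams or {})
    if method == "SVMrej":
        return SVC(
            kernel=hp.pop("kernel", "linear"),
            C=hp.pop("C", 1.0),
            probability=True,
            random_state=seed,
            **hp,
        )
    if method == "RF":
        return RandomForestClassifier(
            n_estimators=hp.pop("n_estimators", 100),
            class_weight=hp.pop("class_weight", "balanced"),
            random_state=seed,
            **hp,
        )
    if method == "KNN":
        return _PCAKNNClassifier(
            n_components=hp.pop("n_components", 30),
            n_neighbors=hp.pop("n_neighbors", 10),
            random_state=seed,
        )
    if method == "NN":
        return MLPClassifier(
            hidden_layer_sizes=hp.pop("hidden_layer_sizes", (100, 50, 25)),
            activation=hp.pop("activation", "relu"),
            solver=hp.pop("solver", "adam"),
            batch_size=hp.pop("batch_size", 128),
            max_iter=hp.pop("max_iter", 50),
            random_state=seed,
            **hp,
        )
    raise ParameterError(f"unknown method {method!r}; choose one of {METHODS}")


def _canonical_method(method: str) -> str:
    for m in METHODS:
        if method.lower() == m.lower():
            return m
    raise ParameterError(f"unknown method {method!r}; choose one of {METHODS}")


@dataclass
class ClassifierModel:
    """A trained, portable cell-cycle classifier.

    Carries the ordered feature-gene list, the per-feature training
    mean/SD used for standardization, the ordered class set, the fitted
    estimator and the rejection cutoff.
    """

    method: str
    feature_genes: list[str]
    feature_means: np.ndarray
    feature_sds: np.ndarray
    class_labels: list[str]
    estimator: object
    rejection_cutoff: float
    seed: int = 0
    format_version: int = MODEL_FORMAT_VERSION

    def __post_init__(self):
        if len(self.feature_means) != len(self.feature_genes) or len(
            self.feature_sds
        ) != len(self.feature_genes):
            raise ParameterError("feature means/SDs length != number of features")

    @property
    def feature_fill(self) -> dict[str, float]:
        """Per-feature fill values (training means) for missing query genes."""
        return dict(zip(self.feature_genes, np.asarray(self.feature_means, float)))

    def standardize(self, aligned: NormalizedMatrix) -> np.ndarray:
        """Cells x features z-scores; missing features forced to z = 0."""
        if list(aligned.gene_ids) != list(self.feature_genes):
            raise ContractError(
                "query matrix is not aligned to the model feature space; "
                "run align_genes first"
            )
        X = aligned.values.T.astype(float)
        sds = np.where(self.feature_sds > 0, self.feature_sds, 1.0)
        Z = (X - self.feature_means[None, :]) / sds[None, :]
        Z[:, np.asarray(self.feature_sds) == 0] = 0.0
        if aligned.missing_genes:
            missing = {g for g in aligned.missing_genes}
            cols = [i for i, g in enumerate(self.feature_genes) if g in missing]
            Z[:, cols] = 0.0
        return Z

    def align(self, query: NormalizedMatrix, homology=None) -> NormalizedMatrix:
        """Convenience wrapper: align a query to this model's feature space."""
        if not self.feature_genes:  # degenerate majority-class model
            return NormalizedMatrix(
                values=np.zeros((0, query.n_cells)),
                gene_ids=[],
                cell_ids=list(query.cell_ids),
                scale_factor=query.scale_factor,
            )
        return align_genes(
            query, self.feature_genes, homology=homology, feature_fill=self.feature_fill
        )


def train_classifier(
    norm: NormalizedMatrix,
    labels,
    method: str = "NN",
    feature_genes: list[str] | None = None,
    hyperparams: dict | None = None,
    seed: int = 0,
) -> ClassifierModel:
    """Train a classifier on a labeled normalized matrix.

    ``feature_genes`` defaults to the top 1,536 most variable genes of
    ``norm`` (or all genes when fewer).  An empty feature list is the
    sanctioned degenerate case: the model falls back to predicting the
    majority training class.  All stochastic elements (NN init, RF
    bootstrap, probability calibration) are fixed by ``seed``.
    """
    method = _canonical_method(method)
    y = np.asarray(labels.labels if isinstance(labels, PhaseLabeling) else labels)
    y = y.astype(object)
    if len(y) != norm.n_cells:
        raise ParameterError(
            f"{len(y)} labels for {norm.n_cells} cells"
        )
    classes, counts = np.unique(y.astype(str), return_counts=True)
    small = [c for c, n in zip(classes, counts) if n < 2]
    if small:
        raise ParameterError(f"class {small[0]!r} has fewer than 2 cells")
    if len(classes) < 2:
        raise ParameterError("need at least 2 classes to train")

    if feature_genes is None:
        n_hvg = min(1536, norm.n_genes)
        feature_genes = select_hvg(norm, n_hvg)
    feature_genes = [str(g) for g in feature_genes]

    idx = {g: i for i, g in enumerate(norm.gene_ids)}
    missing = [g for g in feature_genes if g not in idx]
    if missing:
        raise ParameterError(
            f"{len(missing)} feature genes absent from the training matrix "
            f"(e.g. {missing[0]!r})"
        )
    rows = [idx[g] for g in feature_genes]
    X = norm.values[rows, :].T.astype(float)  # cells x features
    means = X.mean(axis=0) if X.shape[1] else np.zeros(0)
    sds = X.std(axis=0) if X.shape[1] else np.zeros(0)
    safe = np.where(sds > 0, sds, 1.0)
    Z = (X - means[None, :]) / safe[None, :] if X.shape[1] else X

    if X.shape[1] == 0:
        estimator = DummyClassifier(strategy="most_frequent")
        estimator.fit(np.zeros((len(y), 1)), y.astype(str))
    else:
        estimator = _make_estimator(method, hyperparams, seed)
        estimator.fit(Z, y.astype(str))

    return ClassifierModel(
        method=method,
        feature_genes=feature_genes,
        feature_means=np.asarray(means, float),
        feature_sds=np.asarray(sds, float),
        class_labels=[str(c) for c in estimator.classes_],
        estimator=estimator,
        rejection_cutoff=DEFAULT_REJECTION[method],
        seed=seed,
    )


def predict_with_rejection(
    model: ClassifierModel,
    aligned: NormalizedMatrix,
    rejection_cutoff: float | None = None,
) -> PhaseLabeling:
    """Assign phases with a rejection option.

    Each cell receives the argmax class when its top class probability
    is >= the cutoff (inclusive), else ``Unknown``.  A cutoff of 0
    disables rejection.  ``rejection_cutoff=None`` uses the model's own
    default (0.7 for SVMrej, 0 otherwise).
    """
    theta = model.rejection_cutoff if rejection_cutoff is None else rejection_cutoff
    if not 0 <= theta <= 1:
        raise ParameterError("rejection cutoff must lie in [0, 1]")
    if model.feature_genes:
        Z = model.standardize(aligned)
    else:
        Z = np.zeros((aligned.n_cells, 1))
    proba = np.asarray(model.estimator.predict_proba(Z), dtype=float)
    sums = proba.sum(axis=1, keepdims=True)
    proba = proba / np.where(sums > 0, sums, 1.0)
    classes = [str(c) for c in model.estimator.classes_]
    top = proba.argmax(axis=1)
    top_p = proba[np.arange(len(top)), top]
    labels = np.array(
        [classes[j] if p >= theta else UNKNOWN_LABEL for j, p in zip(top, top_p)],
        dtype=object,
    )
    proba_df = pd.DataFrame(proba, index=list(aligned.cell_ids), columns=classes)
    return PhaseLabeling(
        labels=labels,
        cell_ids=list(aligned.cell_ids),
        probabilities=proba_df,
        rejection_cutoff=theta,
    )


@dataclass
class CVReport:
    """Monte-Carlo cross-validation results.

    ``f1`` is a long table (iteration, class, f1); ``errors`` has one
    holdout error rate per iteration.
    """

    f1: pd.DataFrame
    errors: pd.DataFrame
    method: str
    n_iter: int
    holdout_size: int

    @property
    def mean_error(self) -> float:
        return float(self.errors["error_rate"].mean())

    def summary(self) -> pd.DataFrame:
        """Per-class median and IQR of the F1 distribution."""
        def iqr(s):
            return s.quantile(0.75) - s.quantile(0.25)

        g = self.f1.groupby("class")["f1"]
        return pd.DataFrame(
            {"median_f1": g.median(), "iqr_f1": g.apply(iqr)}
        ).reset_index()


def _restrict(norm: NormalizedMatrix, cols: np.ndarray) -> NormalizedMatrix:
    return NormalizedMatrix(
        values=norm.values[:, cols],
        gene_ids=list(norm.gene_ids),
        cell_ids=[norm.cell_ids[i] for i in cols],
        scale_factor=norm.scale_factor,
        log_base=norm.log_base,
    )


def cross_validate(
    norm: NormalizedMatrix,
    labels,
    method: str = "NN",
    n_iter: int = 100,
    holdout_size: int = 1000,
    seed: int = 0,
    feature_genes: list[str] | None = None,
    hyperparams: dict | None = None,
    rejection_cutoff: float | None = None,
) -> CVReport:
    """Repeated random-subsampling cross-validation.

    Each of ``n_iter`` iterations draws a uniform random holdout of
    ``holdout_size`` cells (no stratification), trains on the remainder
    and scores the holdout; per-class F1 and the holdout error rate
    (1 - accuracy, with rejected cells counting as errors) are recorded.
    The fold sequence is reproducible from ``seed``.
    """
    method = _canonical_method(method)
    y = np.asarray(labels.labels if isinstance(labels, PhaseLabeling) else labels)
    y = y.astype(object)
    n = norm.n_cells
    if holdout_size >= n:
        raise ParameterError(f"holdout_size {holdout_size} >= n_cells {n}")
    if n_iter < 1:
        raise ParameterError("n_iter must be >= 1")
    if feature_genes is None:
        feature_genes = select_hvg(norm, min(1536, norm.n_genes))

    classes = sorted(set(map(str, y)))
    rng = np.random.default_rng(seed)
    f1_rows, err_rows = [], []
    for it in range(n_iter):
        hold = rng.choice(n, size=holdout_size, replace=False)
        mask = np.zeros(n, dtype=bool)
        mask[hold] = True
        model = train_classifier(
            _restrict(norm, np.where(~mask)[0]),
            y[~mask],
            method=method,
            feature_genes=feature_genes,
            hyperparams=hyperparams,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        pred = predict_with_rejection(
            model, model.align(_restrict(norm, np.where(mask)[0])), rejection_cutoff
        )
        y_true = y[mask].astype(str)
        y_pred = pred.labels.astype(str)
        err_rows.append(
            {"iteration": it, "error_rate": float(np.mean(y_true != y_pred))}
        )
        for cls in classes:
            f1_rows.append(
                {"iteration": it, "class": cls, "f1": f1_score(y_true, y_pred, cls)}
            )
    return CVReport(
        f1=pd.DataFrame(f1_rows),
        errors=pd.DataFrame(err_rows),
        method=method,
        n_iter=n_iter,
        holdout_size=holdout_size,
    )


@dataclass
class SensitivityCurve:
    """Error rates under random feature-gene removal.

    ``samples`` is a long table (removal_fraction, repeat, error_rate)
    with one mean-CV-error sample per (fraction, repeat).
    """

    samples: pd.DataFrame
    method: str
    n_features: int

    def mean_by_fraction(self) -> pd.Series:
        return self.samples.groupby("removal_fraction")["error_rate"].mean()


def dropout_sensitivity(
    norm: NormalizedMatrix,
    labels,
    method: str = "NN",
    fraction_grid=(0.0, 0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9),
    repeats: int = 3,
    seed: int = 0,
    feature_genes: list[str] | None = None,
    n_iter: int = 3,
    holdout_size: int | None = None,
    hyperparams: dict | None = None,
) -> SensitivityCurve:
    """Classifier robustness to missing genes.

    For each removal fraction f and each repeat, ``floor(f * n_features)``
    randomly chosen feature genes are removed and cross-validation is
    rerun (with a reduced ``n_iter``); the mean holdout error of that
    run is one sample of the curve.  f = 1 removes every feature, under
    which training falls back to majority-class prediction.
    """
    fractions = [float(f) for f in fraction_grid]
    for f in fractions:
        if not 0 <= f <= 1:
            raise ParameterError(f"removal fraction {f} outside [0, 1]")
    if repeats < 1:
        raise ParameterError("repeats must be >= 1")
    if feature_genes is None:
        feature_genes = select_hvg(norm, min(1536, norm.n_genes))
    if holdout_size is None:
        holdout_size = max(1, min(1000, norm.n_cells // 5))

    rng = np.random.default_rng(seed)
    rows = []
    for f in fractions:
        n_remove = int(np.floor(f * len(feature_genes)))
        for rep in range(repeats):
            if n_remove:
                drop = set(
                    rng.choice(len(feature_genes), size=n_remove, replace=False)
                )
                kept = [g for i, g in enumerate(feature_genes) if i not in drop]
            else:
                kept = list(feature_genes)
            report = cross_validate(
                norm,
                labels,
                method=method,
                n_iter=n_iter,
                holdout_size=holdout_size,
                seed=seed,  # same fold sequence at every fraction
                feature_genes=kept,
                hyperparams=hyperparams,
            )
            rows.append(
                {
                    "removal_fraction": f,
                    "repeat": rep,
                    "error_rate": report.mean_error,
                }
            )
    return SensitivityCurve(
        samples=pd.DataFrame(rows), method=method, n_features=len(feature_genes)
    )


def save_model(model: ClassifierModel, path) -> None:
    """Serialize a trained model (single archive, format-versioned)."""
    payload = {
        "format_version": MODEL_FORMAT_VERSION,
        "method": model.method,
        "feature_genes": model.feature_genes,
        "feature_means": np.asarray(model.feature_means),
        "feature_sds": np.asarray(model.feature_sds),
        "class_labels": model.class_labels,
        "estimator": model.estimator,
        "rejection_cutoff": model.rejection_cutoff,
        "seed": model.seed,
    }
    with open(path, "wb") as fh:
        pickle.dump(payload, fh)


def load_model(path) -> ClassifierModel:
    with open(path, "rb") as fh:
        payload = pickle.load(fh)
    version = payload.pop("format_version")
    if version != MODEL_FORMAT_VERSION:
        raise ContractError(f"unsupported model format version {version}")
    return ClassifierModel(format_version=version, **payload)
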