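"""The four classification backends and the trial-level split protocol.

Four standard classifiers are supported — SVM (RBF kernel, one-vs-one),
KNN, LDA, and a small feed-forward ANN (one hidden layer of 30 nodes,
gradient descent, learning rate 0.01).  Hyperparameters (SVM penalty C and
kernel width gamma; KNN neighbour count) are tuned by five-fold
cross-validated grid search on the training rows; models train on
steady-state rows only — transition-cycle rows are excluded by the caller.

The contribution of this package is the harness around these models (the
protocol, feature stream, vote layer and scoring); the solvers themselves
are scikit-learn.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.exceptions import ConvergenceWarning
from sklearn.model_selection import GridSearchCV, StratifiedKFold, cross_val_score
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.svm import SVC

__all__ = ["ClassifierSpec", "TrainedModel", "split_trials",
           "tune_and_train", "predict_stream",
           "DEFAULT_SVM_C_GRID", "DEFAULT_SVM_G_GRID"]

METHODS = ("SVM", "KNN", "LDA", "ANN")

# Conventional RBF grid (powers of two, exponent step 2).
DEFAULT_SVM_C_GRID: tuple[float, ...] = tuple(2.0 ** e for e in range(-5, 16, 2))
DEFAULT_SVM_G_GRID: tuple[float, ...] = tuple(2.0 ** e for e in range(-15, 4, 2))
DEFAULT_KNN_K_GRID: tuple[int, ...] = tuple(range(1, 26, 2))


@dataclass(frozen=True)
class ClassifierSpec:
    """Which classifier to build and how to tune it.

    ``params`` may override the search grids (``c_grid``/``g_grid`` for
    SVM, ``k_grid`` for KNN) or the ANN budget (``max_iter``).
    """

    method: str = "SVM"
    params: dict = field(default_factory=dict)
    cv_folds: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.method not in METHODS:
            raise ValueError(f"method must be one of {METHODS}, got {self.method!r}")
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")


@dataclass
class TrainedModel:
    spec: ClassifierSpec
    estimator: object                 # fitted sklearn estimator
    classes: np.ndarray
    best_params: dict
    cv_accuracy: float


def split_trials(
    trials: Sequence, n_sets: int = 6, seed: int = 0
) -> tuple[list, list]:
    """Randomly partition trials into n_sets; the last set is held out.

    Mirrors the study protocol (30 trials -> 5 training sets of 5 + 1 test
    set of 5).  Reproducible under ``seed``; raises if there are fewer
    trials than sets.
    """
    trials = list(trials)
    if len(trials) < n_sets:
        raise ValueError(f"need at least {n_sets} trials, got {len(trials)}")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(trials))
    sets = np.array_split(order, n_sets)
    test_idx = set(sets[-1].tolist())
    train = [trials[i] for i in order if i not in test_idx]
    test = [trials[i] for i in sets[-1]]
    return train, test


def _build(spec: ClassifierSpec, n_train: int):
    """Estimator + parameter grid for a spec."""
    p = spec.params
    if spec.method == "SVM":
        est = SVC(kernel="rbf", decision_function_shape="ovo")
        grid = {
            "C": list(p.get("c_grid", DEFAULT_SVM_C_GRID)),
            "gamma": list(p.get("g_grid", DEFAULT_SVM_G_GRID)),
        }
    elif spec.method == "KNN":
        est = KNeighborsClassifier()
        ks = [k for k in p.get("k_grid", DEFAULT_KNN_K_GRID) if k <= n_train]
        grid = {"n_neighbors": ks or [1]}
    elif spec.method == "LDA":
        est = LinearDiscriminantAnalysis()
        grid = {}
    else:  # ANN: one hidden layer of 30, full-batch (momentum) gradient descent
        est = MLPClassifier(
            hidden_layer_sizes=(30,),
            solver="sgd",
            learning_rate_init=0.01,
            learning_rate="constant",
            momentum=0.9,
            nesterovs_momentum=True,
            batch_size=max(1, n_train),
            max_iter=int(p.get("max_iter", 2000)),
            n_iter_no_change=50,
            tol=1e-7,
            random_state=spec.seed,
        )
        grid = {}
    return est, grid


def tune_and_train(X: np.ndarray, y: np.ndarray, spec: ClassifierSpec) -> TrainedModel:
    """Grid-search (5-fold CV) and refit on all training rows.

    Expects normalised steady-state rows.  Raises if any class has fewer
    samples than the number of folds.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    classes, counts = np.unique(y, return_counts=True)
    if classes.size < 2:
        raise ValueError("training data must contain at least two classes")
    if counts.min() < spec.cv_folds:
        lacking = classes[counts.argmin()]
        raise ValueError(
            f"class {lacking} has {counts.min()} samples; "
            f"need >= {spec.cv_folds} for {spec.cv_folds}-fold CV"
        )
    est, grid = _build(spec, len(y))
    cv = StratifiedKFold(n_splits=spec.cv_folds, shuffle=True, random_state=spec.seed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        # CV folds are smaller than the full-batch size; sklearn clips it.
        warnings.filterwarnings("ignore", message=".*batch_size.*", category=UserWarning)
        if grid:
            search = GridSearchCV(est, grid, cv=cv, scoring="accuracy", n_jobs=None)
            search.fit(X, y)
            fitted = search.best_estimator_
            best = dict(search.best_params_)
            cv_acc = float(search.best_score_)
        else:
            cv_acc = float(np.mean(cross_val_score(est, X, y, cv=cv, scoring="accuracy")))
            fitted = est.fit(X, y)
            best = {}
    return TrainedModel(spec=spec, estimator=fitted, classes=np.asarray(fitted.classes_),
                        best_params=best, cv_accuracy=cv_acc)


def predict_stream(model: TrainedModel, X: np.ndarray) -> np.ndarray:
    """Raw per-row label sequence (pre-vote); a pure function of each row."""
    X = np.asarray(X, dtype=float)
    expected = getattr(model.estimator, "n_features_in_", None)
    if expected is not None and X.shape[1] != expected:
        raise ValueError(
            f"feature count mismatch: model expects {expected}, got {X.shape[1]}"
        )
    return np.asarray(model.estimator.predict(X))
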