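"""Fusion of network latent features with clinical features, and the
seven-classifier randomized-search protocol.

For each of the network's last three layers (widths 14/32/64) the
per-patient latent vector is optionally concatenated with the
preselected clinical features.  Seven classical classifiers -- random
forest, MLP, logistic regression, decision tree, k-nearest neighbors,
SVM and AdaBoost -- are each tuned by seeded random search with
stratified 5-fold cross-validation on the training set, refitted on the
full training set, and evaluated once on the held-out test set,
producing a method x layer result grid.

Distance- and gradient-based classifiers (kNN, SVM, logistic
regression, MLP) receive z-scored features with statistics computed
inside each training fold (a scaler inside the estimator pipeline);
tree-based methods receive raw values.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import randint, uniform
from sklearn.base import clone
from sklearn.ensemble import AdaBoostClassifier, RandomForestClassifier
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import ParameterSampler, StratifiedKFold
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier
from sklearn.metrics import balanced_accuracy_score

from .clinical import FeatureMatrix
from .metrics import MetricsReport, evaluate_predictions
from .model import FusionNet, LATENT_LAYERS

log = logging.getLogger(__name__)

METHODS = ("random_forest", "mlp", "logistic_regression", "decision_tree",
           "knn", "svm", "adaboost")

#: Methods whose estimator pipeline includes fold-internal z-scoring.
SCALED_METHODS = frozenset({"mlp", "logistic_regression", "knn", "svm"})


@dataclass
class FusedMatrix:
    """Latent block then clinical block, with the boundary recorded."""
    frame: pd.DataFrame
    layer: int
    latent_columns: list[str]
    clinical_columns: list[str]

    @property
    def values(self) -> np.ndarray:
        return self.frame.to_numpy(dtype=float)

    @property
    def ids(self):
        return self.frame.index

    def block_of(self, column: str) -> str:
        return "latent" if column in set(self.latent_columns) else "clinical"


def fuse(latent: np.ndarray, ids: Sequence, layer: int,
         clinical: FeatureMatrix | None = None) -> FusedMatrix:
    """Concatenate per-patient latent vectors with clinical features
    (aligned by patient id); ``clinical=None`` gives the latent-only
    matrix of the CXR-only experiment."""
    latent = np.asarray(latent, dtype=float)
    lat_cols = [f"latent{layer}_{j}" for j in range(latent.shape[1])]
    frame = pd.DataFrame(latent, columns=lat_cols,
                         index=pd.Index(ids, name="patient_id"))
    frame = frame.sort_index()
    clin_cols: list[str] = []
    if clinical is not None:
        cf = clinical.frame.sort_index()
        missing = frame.index.symmetric_difference(cf.index)
        if len(missing):
            raise ValueError(
                f"latent/clinical id mismatch; offenders: {list(missing)[:10]}")
        clin_cols = list(cf.columns)
        frame = pd.concat([frame, cf], axis=1)
    return FusedMatrix(frame=frame, layer=layer, latent_columns=lat_cols,
                       clinical_columns=clin_cols)


def default_search_space(n_features: int) -> dict[str, dict]:
    """Per-method hyperparameter envelopes for the random search."""
    return {
        "random_forest": {
            "n_estimators": randint(1, 31),
            "max_depth": randint(1, 21),
            "criterion": ["gini", "entropy"],
            "max_features": randint(1, max(2, n_features + 1)),
        },
        "mlp": {
            "hidden_layer_sizes": randint(10, 201),
            "solver": ["lbfgs", "sgd", "adam"],
            "max_iter": randint(1, 151),
        },
        "logistic_regression": {
            "C": uniform(0.1, 9.9),
            "solver": ["lbfgs", "saga", "newton-cg"],
            "max_iter": randint(1, 101),
        },
        "decision_tree": {
            "max_depth": randint(1, 21),
            "criterion": ["gini", "entropy"],
            "max_features": ["sqrt", "log2", None],
        },
        "knn": {
            "n_neighbors": randint(1, 16),
            "weights": ["uniform", "distance"],
            "algorithm": ["auto", "ball_tree"],
        },
        "svm": {
            "C": uniform(0.1, 9.9),
            "kernel": ["rbf", "poly", "linear"],
        },
        "adaboost": {
            "n_estimators": randint(1, 31),
            "learning_rate": uniform(0.1, 0.9),
        },
    }


@dataclass
class SearchSpace:
    spaces: Mapping[str, dict] | None = None
    n_iterations: int = 50
    folds: int = 5
    scoring: str = "balanced_accuracy"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.folds < 2:
            raise ValueError("folds must be >= 2")

    def space_for(self, method: str, n_features: int) -> dict:
        if self.spaces is not None and method in self.spaces:
            return self.spaces[method]
        return default_search_space(n_features)[method]


def make_estimator(method: str, params: dict, seed: int = 0):
    """Instantiate one of the seven classifiers with sampled
    hyperparameters (wrapped in a scaler pipeline where appropriate)."""
    params = dict(params)
    if method == "random_forest":
        est = RandomForestClassifier(random_state=seed, **params)
    elif method == "mlp":
        if "hidden_layer_sizes" in params and np.ndim(params["hidden_layer_sizes"]) == 0:
            params["hidden_layer_sizes"] = (int(params["hidden_layer_sizes"]),)
        est = MLPClassifier(random_state=seed, **params)
    elif method == "logistic_regression":
        est = LogisticRegression(random_state=seed, **params)
    elif method == "decision_tree":
        est = DecisionTreeClassifier(random_state=seed, **params)
    elif method == "knn":
        est = KNeighborsClassifier(**params)
    elif method == "svm":
        est = SVC(random_state=seed, **params)
    elif method == "adaboost":
        est = AdaBoostClassifier(random_state=seed, **params)
    else:
        raise ValueError(f"unknown method {method!r}; supported: {METHODS}")
    if method in SCALED_METHODS:
        return Pipeline([("scale", StandardScaler()), ("clf", est)])
    return est


def _fit_quiet(est, X, y):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        warnings.simplefilter("ignore", UserWarning)
        est.fit(X, y)
    return est


def decision_scores(est, X) -> np.ndarray:
    """Continuous score for ROC-AUC: probability where available,
    decision margin otherwise."""
    clf = est[-1] if isinstance(est, Pipeline) else est
    if hasattr(clf, "predict_proba"):
        return est.predict_proba(X)[:, 1]
    return est.decision_function(X)


def random_search_cv(X: np.ndarray, y: np.ndarray, method: str,
                     space: SearchSpace) -> dict:
    """Seeded random search over the method's space, scored by mean
    stratified-CV balanced accuracy; ties go to the first-sampled
    candidate.  Returns best params, best score and the full trace."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if len(X) < space.folds:
        raise ValueError("fewer rows than folds")
    if method not in METHODS:
        raise ValueError(f"unknown method {method!r}; supported: {METHODS}")
    sampler = ParameterSampler(space.space_for(method, X.shape[1]),
                               n_iter=space.n_iterations,
                               random_state=space.seed)
    skf = StratifiedKFold(n_splits=space.folds, shuffle=True,
                          random_state=space.seed)
    folds = list(skf.split(X, y))
    trace = []
    for cand in sampler:
        scores = []
        for tr, va in folds:
            est = make_estimator(method, cand, seed=space.seed)
            try:
                _fit_quiet(est, X[tr], y[tr])
                scores.append(balanced_accuracy_score(y[va], est.predict(X[va])))
            except ValueError:        # degenerate candidate (e.g. k > fold)
                scores.append(0.0)
        trace.append({"params": cand, "mean_score": float(np.mean(scores))})
    best_i = int(np.argmax([t["mean_score"] for t in trace]))
    return {"method": method,
            "best_params": trace[best_i]["params"],
            "best_score": trace[best_i]["mean_score"],
            "trace": trace}


def run_experiment(model: FusionNet,
                   images_train: np.ndarray, y_train: np.ndarray,
                   images_test: np.ndarray, y_test: np.ndarray,
                   ids_train: Sequence | None = None,
                   ids_test: Sequence | None = None,
                   clinical_train: FeatureMatrix | None = None,
                   clinical_test: FeatureMatrix | None = None,
                   space: SearchSpace | None = None,
                   layers: Sequence[int] = LATENT_LAYERS,
                   methods: Sequence[str] = METHODS) -> pd.DataFrame:
    """The full protocol for one experiment (CXR-only when clinical is
    None, mixed-data otherwise): per layer and method, tune on the
    training set, refit, evaluate once on the test set.

    Returns the result grid: one row per method x layer with accuracy,
    F1, precision, recall, balanced accuracy, ROC-AUC and the chosen
    hyperparameters.
    """
    space = space or SearchSpace()
    y_train = np.asarray(y_train)
    y_test = np.asarray(y_test)
    if len(np.unique(y_test)) < 2:
        raise ValueError("test set must contain both classes")
    ids_train = (np.arange(len(y_train)) if ids_train is None
                 else np.asarray(ids_train))
    ids_test = (np.arange(len(y_test)) + len(y_train) if ids_test is None
                else np.asarray(ids_test))
    ytr = pd.Series(y_train, index=ids_train).sort_index().to_numpy()
    yte = pd.Series(y_test, index=ids_test).sort_index().to_numpy()

    rows = []
    for layer in layers:
        ltr = model.extract_latent(images_train, layer=layer)
        lte = model.extract_latent(images_test, layer=layer)
        ftr = fuse(ltr, ids_train, layer, clinical_train)
        fte = fuse(lte, ids_test, layer, clinical_test)
        for method in methods:
            found = random_search_cv(ftr.values, ytr, method, space)
            est = make_estimator(method, found["best_params"], seed=space.seed)
            _fit_quiet(est, ftr.values, ytr)
            pred = est.predict(fte.values)
            rep: MetricsReport = evaluate_predictions(
                yte, pred, scores=decision_scores(est, fte.values))
            rows.append({"layer": layer, "method": method,
                         **rep.rounded(),
                         "cv_score": round(found["best_score"], 4),
                         "best_params": json.dumps(
                             found["best_params"], default=str, sort_keys=True)})
            log.info("layer %d %s: acc %.4f bal %.4f", layer, method,
                     rep.accuracy, rep.balanced_accuracy)
    return pd.DataFrame(rows)
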