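"""Rupture-status classification protocol.

Five classifier families — SVM, KNN, RF, XGB and MLP — are tuned by grid
search under stratified five-fold cross-validation on a stratified 80/20
training split, with per-feature standardization fitted inside each
training fold (no test leakage).  Evaluation reports train/test accuracy,
precision and recall for the ruptured class, the ROC curve with its AUC,
and a flag when the train-test accuracy gap exceeds 0.10 (the overfitting
rule of thumb this protocol adopts).  Feature importances are signed where
the model admits a sign: linear-SVM coefficients, MLP connection-weight
products (exact for the identity activation, which makes the network a
composed linear map), permutation importance for kernelized/instance-based
models, and native split-gain importances for the tree ensembles.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from functools import reduce
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.inspection import permutation_importance
from sklearn.model_selection import GridSearchCV, StratifiedKFold, train_test_split
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from xgboost import XGBClassifier

from .datatypes import LOCATIONS, MORPH_FIELDS, SEXES
from .errors import EncodingError, MetricError, TrainingError

MODEL_FAMILIES = ("SVM", "KNN", "RF", "XGB", "MLP")

LOCATION_COLUMNS = tuple(
    "loc_" + loc.replace("/", "_") for loc in LOCATIONS)

#: Encoded design-matrix columns: 35 morphological + age + sex + 6 one-hot
#: location indicators = 43 features.
ENCODED_FEATURES = MORPH_FIELDS + ("age", "sex") + LOCATION_COLUMNS
ENCODED_WIDTH = len(ENCODED_FEATURES)
assert ENCODED_WIDTH == 43


# ---------------------------------------------------------------------------
# preprocessing

def encode_features(table: pd.DataFrame) -> pd.DataFrame:
    """Encode a raw cohort table into the fixed numeric design matrix.

    sex: F -> 1, M -> 0; location: one-hot over the six-site vocabulary;
    LB and I are already binary.  The label column is carried through.
    """
    for col in MORPH_FIELDS + ("age", "sex", "location"):
        if col not in table.columns:
            raise EncodingError(f"missing column: {col}")
    bad_sex = set(table["sex"].unique()) - set(SEXES)
    if bad_sex:
        raise EncodingError(f"unknown sex categories: {sorted(bad_sex)}")
    bad_loc = set(table["location"].unique()) - set(LOCATIONS)
    if bad_loc:
        raise EncodingError(f"unknown location categories: {sorted(bad_loc)}")
    out = table[list(MORPH_FIELDS)].astype(float).copy()
    out["age"] = table["age"].astype(float)
    out["sex"] = (table["sex"] == "F").astype(float)
    for loc, col in zip(LOCATIONS, LOCATION_COLUMNS):
        out[col] = (table["location"] == loc).astype(float)
    if "ruptured" in table.columns:
        out["ruptured"] = table["ruptured"].astype(int)
    return out[list(ENCODED_FEATURES) + (["ruptured"] if "ruptured" in out else [])]


def decode_location(encoded_row: Mapping[str, float]) -> str:
    """Inverse of the one-hot location encoding for a single row."""
    for loc, col in zip(LOCATIONS, LOCATION_COLUMNS):
        if encoded_row[col] == 1:
            return loc
    raise EncodingError("row has no active location indicator")


@dataclass(frozen=True)
class StandardizationRecord:
    """Per-column mean/sd fitted on the training rows only."""

    mean: pd.Series
    sd: pd.Series

    def apply(self, table: pd.DataFrame) -> pd.DataFrame:
        out = table.copy()
        for col in self.mean.index:
            if self.sd[col] > 0:
                out[col] = (table[col] - self.mean[col]) / self.sd[col]
            else:
                out[col] = 0.0  # zero-variance column carries no information
        return out

    def invert(self, table: pd.DataFrame) -> pd.DataFrame:
        out = table.copy()
        for col in self.mean.index:
            out[col] = table[col] * self.sd[col] + self.mean[col]
        return out


def standardize(
    table: pd.DataFrame, fit_rows: Sequence[int]
) -> Tuple[pd.DataFrame, StandardizationRecord]:
    """Z-score every numeric feature column using ``fit_rows`` statistics."""
    fit_rows = np.asarray(fit_rows)
    if len(fit_rows) == 0:
        raise TrainingError("standardize needs a nonempty fit-row subset")
    cols = [c for c in table.columns if c != "ruptured"
            and pd.api.types.is_numeric_dtype(table[c])]
    sub = table.iloc[fit_rows]
    record = StandardizationRecord(
        mean=sub[cols].mean(), sd=sub[cols].std(ddof=0))
    return record.apply(table), record


# ---------------------------------------------------------------------------
# training

def default_grids(seed: int) -> Dict[str, Tuple[Pipeline, dict]]:
    """Documented default hyperparameter grids per model family.

    The protocol prescribes grid search and five-fold CV but no particular
    grids; these are deliberately compact, covering the decisions that move
    each family most.  The MLP uses three hidden layers with an identity
    activation and an adaptive SGD learning rate (a composed linear model).
    """
    def pipe(model):
        return Pipeline([("scale", StandardScaler()), ("model", model)])

    return {
        "SVM": (
            pipe(SVC(random_state=seed)),
            {"model__kernel": ["linear", "rbf"], "model__C": [0.1, 1.0, 10.0]},
        ),
        "KNN": (
            pipe(KNeighborsClassifier()),
            {"model__n_neighbors": [3, 5, 7, 9, 11, 13, 15]},
        ),
        "RF": (
            pipe(RandomForestClassifier(n_estimators=200, random_state=seed,
                                        n_jobs=1)),
            {"model__max_depth": [None, 6, 12]},
        ),
        "XGB": (
            pipe(XGBClassifier(n_estimators=200, random_state=seed,
                               tree_method="hist", n_jobs=1,
                               eval_metric="logloss")),
            {"model__max_depth": [3, 6],
             "model__learning_rate": [0.1, 0.3]},
        ),
        "MLP": (
            pipe(MLPClassifier(activation="identity", solver="sgd",
                               learning_rate="adaptive", max_iter=1500,
                               random_state=seed)),
            {"model__hidden_layer_sizes": [(32, 16, 8), (64, 32, 16)]},
        ),
    }


@dataclass
class ModelResult:
    name: str
    estimator: Pipeline
    best_params: dict
    cv_score: float


@dataclass
class TrainedModels:
    models: Dict[str, ModelResult]
    X_train: pd.DataFrame
    X_test: pd.DataFrame
    y_train: np.ndarray
    y_test: np.ndarray
    seed: int


def train_models(
    table: pd.DataFrame,
    families: Sequence[str] = MODEL_FAMILIES,
    seed: int = 0,
    test_size: float = 0.2,
) -> TrainedModels:
    """Stratified 80/20 split, then per-family grid search with stratified
    five-fold CV on the training portion."""
    if "ruptured" not in table.columns:
        raise TrainingError("table has no 'ruptured' label column")
    if len(table) < 50:
        raise TrainingError("need at least 50 rows to train")
    unknown = set(families) - set(MODEL_FAMILIES)
    if unknown:
        raise TrainingError(f"unknown model families: {sorted(unknown)}")
    y = table["ruptured"].to_numpy(dtype=int)
    if len(np.unique(y)) < 2:
        raise TrainingError("both classes must be present")
    X = table.drop(columns=["ruptured"])
    X_train, X_test, y_train, y_test = train_test_split(
        X, y, test_size=test_size, stratify=y, random_state=seed
    )
    cv = StratifiedKFold(n_splits=5, shuffle=True, random_state=seed)
    grids = default_grids(seed)
    models: Dict[str, ModelResult] = {}
    for name in families:
        estimator, grid = grids[name]
        search = GridSearchCV(estimator, grid, cv=cv, scoring="accuracy",
                              n_jobs=1, refit=True)
        search.fit(X_train, y_train)
        models[name] = ModelResult(
            name=name,
            estimator=search.best_estimator_,
            best_params=dict(search.best_params_),
            cv_score=float(search.best_score_),
        )
    return TrainedModels(models=models, X_train=X_train, X_test=X_test,
                         y_train=y_train, y_test=y_test, seed=seed)


# ---------------------------------------------------------------------------
# evaluation

def decision_scores(estimator, X: pd.DataFrame) -> np.ndarray:
    """Continuous scores for ROC ranking: decision_function when available,
    otherwise the positive-class probability."""
    if hasattr(estimator, "decision_function"):
        return np.asarray(estimator.decision_function(X), dtype=float)
    return np.asarray(estimator.predict_proba(X)[:, 1], dtype=float)


def roc_auc(scores: np.ndarray, labels: np.ndarray) -> Tuple[np.ndarray, float]:
    """ROC by threshold sweep over the unique scores; AUC by trapezoid.

    The AUC equals the Mann-Whitney concordance probability (ties counted
    one half).  Returns (points, auc) with points an (k, 2) array of
    (FPR, TPR) from (0, 0) to (1, 1), monotone in both coordinates.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    n_pos = int(labels.sum())
    n_neg = len(labels) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise MetricError("ROC requires both classes in the labels")
    order = np.argsort(-scores, kind="stable")
    sorted_scores = scores[order]
    sorted_labels = labels[order]
    tps = np.cumsum(sorted_labels)
    fps = np.cumsum(1 - sorted_labels)
    # keep only the last index of each tied-score run (one point per threshold)
    distinct = np.r_[np.diff(sorted_scores) != 0, True]
    tpr = np.r_[0.0, tps[distinct] / n_pos]
    fpr = np.r_[0.0, fps[distinct] / n_neg]
    auc = float(np.trapezoid(tpr, fpr))
    return np.column_stack([fpr, tpr]), auc


@dataclass
class ModelEvaluation:
    name: str
    train_accuracy: float
    test_accuracy: float
    precision: float
    recall: float
    roc_points: np.ndarray
    auc: float
    gap_flag: bool
    no_positive_prediction: bool = False

    def as_dict(self) -> dict:
        return {
            "name": self.name,
            "train_accuracy": self.train_accuracy,
            "test_accuracy": self.test_accuracy,
            "precision": self.precision,
            "recall": self.recall,
            "auc": self.auc,
            "gap_flag": self.gap_flag,
            "no_positive_prediction": self.no_positive_prediction,
            "roc_points": [[float(a), float(b)] for a, b in self.roc_points],
        }


def evaluate_model(
    name: str,
    estimator,
    X_train: pd.DataFrame,
    y_train: np.ndarray,
    X_test: pd.DataFrame,
    y_test: np.ndarray,
) -> ModelEvaluation:
    """Accuracy/precision/recall (positive class = ruptured), ROC and the
    10%-gap overfitting flag for one fitted model."""
    if len(X_test) == 0:
        raise MetricError("empty test set")
    pred_train = estimator.predict(X_train)
    pred_test = estimator.predict(X_test)
    train_acc = float(np.mean(pred_train == y_train))
    test_acc = float(np.mean(pred_test == y_test))
    tp = int(np.sum((pred_test == 1) & (y_test == 1)))
    fp = int(np.sum((pred_test == 1) & (y_test == 0)))
    fn = int(np.sum((pred_test == 0) & (y_test == 1)))
    no_pos = (tp + fp) == 0
    precision = 0.0 if no_pos else tp / (tp + fp)
    recall = 0.0 if (tp + fn) == 0 else tp / (tp + fn)
    points, auc = roc_auc(decision_scores(estimator, X_test), y_test)
    return ModelEvaluation(
        name=name,
        train_accuracy=train_acc,
        test_accuracy=test_acc,
        precision=float(precision),
        recall=float(recall),
        roc_points=points,
        auc=auc,
        gap_flag=(train_acc - test_acc) > 0.10,
        no_positive_prediction=no_pos,
    )


def evaluate_all(trained: TrainedModels) -> Dict[str, ModelEvaluation]:
    return {
        name: evaluate_model(
            name, res.estimator, trained.X_train, trained.y_train,
            trained.X_test, trained.y_test,
        )
        for name, res in trained.models.items()
    }


# ---------------------------------------------------------------------------
# feature importance

def mlp_linear_coefficients(mlp: MLPClassifier) -> np.ndarray:
    """Composed linear map of an identity-activation MLP: the product of
    all connection-weight matrices, one signed coefficient per feature."""
    return reduce(np.matmul, mlp.coefs_).ravel()


def importance(
    result: ModelResult,
    X: pd.DataFrame,
    y: np.ndarray,
    seed: int = 0,
) -> List[Tuple[str, float]]:
    """Signed per-feature weights for one fitted model, ordered by |weight|.

    linear SVM -> coefficients; rbf SVM and KNN -> permutation importance
    (signed: a harmful permuted feature goes negative); RF/XGB -> native
    split-gain importances; identity-MLP -> connection-weight products.
    All weights refer to the standardized features (the scaler sits inside
    the pipeline).
    """
    names = list(X.columns)
    model = result.estimator.named_steps["model"]
    if result.name == "SVM" and model.kernel == "linear":
        weights = model.coef_.ravel()
    elif result.name in ("SVM", "KNN"):
        perm = permutation_importance(
            result.estimator, X, y, n_repeats=5, random_state=seed, n_jobs=1)
        weights = perm.importances_mean
    elif result.name in ("RF", "XGB"):
        weights = np.asarray(model.feature_importances_, dtype=float)
    elif result.name == "MLP":
        weights = mlp_linear_coefficients(model)
    else:  # pragma: no cover
        raise TrainingError(f"importance undefined for model {result.name}")
    if len(weights) != len(names):
        raise TrainingError("weight/feature length mismatch")
    ranked = sorted(zip(names, map(float, weights)),
                    key=lambda kv: -abs(kv[1]))
    return ranked


def linear_svm_importance(
    table: pd.DataFrame, C: float = 0.02, seed: int = 0
) -> List[Tuple[str, float]]:
    """Signed linear-SVM attribution over a whole encoded cohort.

    Fits a standardized linear SVM on all rows and returns (feature, weight)
    ordered by |weight|.  The strong L2 penalty (small C) is deliberate:
    morphometric batteries contain clusters of near-collinear features
    (e.g. IR is a deterministic transform of NA), and with weak
    regularization the margin problem is ill-conditioned inside a cluster —
    pairs of proxies can take large opposite-sign weights that say nothing
    about the label.  Ridge-like shrinkage shares weight within a cluster
    and leaves the ranking to the genuine signal.
    """
    if "ruptured" not in table.columns:
        raise TrainingError("table has no 'ruptured' label column")
    y = table["ruptured"].to_numpy(dtype=int)
    X = table.drop(columns=["ruptured"])
    pipeline = Pipeline([
        ("scale", StandardScaler()),
        ("model", SVC(kernel="linear", C=C, random_state=seed)),
    ])
    pipeline.fit(X, y)
    weights = pipeline.named_steps["model"].coef_.ravel()
    return sorted(zip(X.columns, map(float, weights)), key=lambda kv: -abs(kv[1]))


def importance_all(
    trained: TrainedModels, seed: int = 0
) -> Dict[str, List[Tuple[str, float]]]:
    return {
        name: importance(res, trained.X_train, trained.y_train, seed=seed)
        for name, res in trained.models.items()
    }


# ---------------------------------------------------------------------------
# cohort summaries and serialization

def cohort_summary(table: pd.DataFrame) -> dict:
    """Location x sex counts and per-location rupture rates."""
    counts = (
        table.groupby(["location", "sex"], observed=True)
        .size().unstack(fill_value=0)
    )
    by_loc = table.groupby("location", observed=True)["ruptured"]
    rates = (by_loc.sum() / by_loc.count()).to_dict()
    return {
        "counts": {loc: counts.loc[loc].to_dict() for loc in counts.index},
        "rupture_rate_by_location": {k: float(v) for k, v in rates.items()},
        "overall_rupture_rate": float(table["ruptured"].mean()),
        "n": int(len(table)),
    }


def reports_to_json(
    evaluations: Dict[str, ModelEvaluation],
    importances: Optional[Dict[str, List[Tuple[str, float]]]] = None,
) -> str:
    """Deterministic JSON serialization of the evaluation/importance reports."""
    payload = {"evaluation": {k: v.as_dict() for k, v in evaluations.items()}}
    if importances is not None:
        payload["importance"] = {
            k: [[f, w] for f, w in v] for k, v in importances.items()
        }
    return json.dumps(payload, sort_keys=True, indent=1)
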