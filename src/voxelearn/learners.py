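"""Classifier training on tagged-voxel features.

Five base classifiers are supported — random forest (RFC), multi-layer
perceptron (MLP), gradient boosting (XGB), support-vector machine (SVM) and
Gaussian naive Bayes (NBC) — plus a stacked *strong learner*: the four
non-boosting classifiers are fitted first and their predicted positive-class
probabilities are appended to the feature vector before a gradient-boosting
meta model is trained on the augmented matrix.  Supervision is deliberately
tiny (a handful of strokes), so by default weak probabilities are computed
on the training rows themselves; an out-of-fold mode is available for users
who prefer leakage-free stacking.

Models persist to a self-describing archive (schema JSON + fitted blob) and
refuse to predict on a mismatching feature schema.
"""

from __future__ import annotations

import io
import json
import zipfile
from dataclasses import dataclass, field
from pathlib import Path

import joblib
import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold
from sklearn.naive_bayes import GaussianNB
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from xgboost import XGBClassifier

from .errors import FormatError, SchemaError, UntrainableError, ValidationError

CLASSIFIER_KINDS = ("RFC", "MLP", "XGB", "SVM", "NBC")
WEAK_KINDS = ("RFC", "MLP", "SVM", "NBC")  # the strong learner's quartet

_ARCHIVE_VERSION = 1

# Defaults chosen for rapid fitting on stroke-sized training sets; every
# entry can be overridden through ClassifierSpec.hyperparameters.
_DEFAULT_HYPERPARAMS = {
    "RFC": {"n_estimators": 100, "max_depth": None},
    "XGB": {"n_estimators": 100, "max_depth": 3, "learning_rate": 0.1},
    "MLP": {"hidden_layer_sizes": (64,), "max_iter": 300},
    "SVM": {"kernel": "rbf", "C": 1.0},
    "NBC": {},
}


@dataclass(frozen=True)
class ClassifierSpec:
    kind: str
    hyperparameters: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self):
        if self.kind not in CLASSIFIER_KINDS:
            raise ValidationError(
                f"classifier kind must be one of {CLASSIFIER_KINDS}, got {self.kind!r}"
            )

    def resolved_hyperparameters(self) -> dict:
        params = dict(_DEFAULT_HYPERPARAMS[self.kind])
        params.update(self.hyperparameters)
        return params


def _build_estimator(spec: ClassifierSpec):
    params = spec.resolved_hyperparameters()
    seed = int(spec.seed)
    if spec.kind == "RFC":
        return RandomForestClassifier(random_state=seed, **params)
    if spec.kind == "XGB":
        return XGBClassifier(
            random_state=seed,
            eval_metric="logloss",
            n_jobs=1,
            **params,
        )
    if spec.kind == "MLP":
        # intensity-scale features stall MLP convergence; standardise inside
        return Pipeline(
            [
                ("scale", StandardScaler()),
                ("mlp", MLPClassifier(random_state=seed, **params)),
            ]
        )
    if spec.kind == "SVM":
        return Pipeline(
            [
                ("scale", StandardScaler()),
                ("svm", SVC(probability=True, random_state=seed, **params)),
            ]
        )
    if spec.kind == "NBC":
        return GaussianNB(**params)
    raise ValidationError(f"unknown classifier kind {spec.kind!r}")


def _validate_training_data(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y, dtype=np.int64)
    if X.ndim != 2:
        raise ValidationError("X must be a 2D matrix")
    if X.shape[0] != y.shape[0]:
        raise ValidationError("X and y row counts differ")
    if X.shape[0] == 0:
        raise UntrainableError("no tagged voxels to train on")
    if not np.all(np.isfinite(X)):
        raise ValidationError("X contains non-finite values")
    classes = np.unique(y)
    if not np.all(np.isin(classes, (0, 1))):
        raise ValidationError("y must be binary {0, 1}")
    if classes.size < 2:
        raise UntrainableError("training needs at least one voxel of each class")
    return X, y


@dataclass
class TrainedModel:
    spec: ClassifierSpec
    estimator: object
    schema_hash: str
    feature_names: list[str]
    metadata: dict = field(default_factory=dict)

    @property
    def n_features(self) -> int:
        return len(self.feature_names)

    def _check_schema(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=np.float64)
        if X.ndim != 2 or X.shape[1] != self.n_features:
            raise SchemaError(
                f"expected {self.n_features} feature columns, got "
                f"{X.shape[1] if X.ndim == 2 else X.shape}"
            )
        return X

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        """Positive-class probability per row, in [0, 1]."""
        X = self._check_schema(X)
        proba = self.estimator.predict_proba(X)
        pos_col = list(self.estimator.classes_).index(1)
        return np.clip(proba[:, pos_col], 0.0, 1.0)


@dataclass
class StrongLearnerModel:
    """Gradient-boosting meta model over four weak learners.

    The meta model consumes the original features plus one appended
    probability column per weak learner (schema = base + 4).
    """

    weak: dict[str, TrainedModel]
    meta: TrainedModel
    schema_hash: str
    feature_names: list[str]
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        if tuple(sorted(self.weak)) != tuple(sorted(WEAK_KINDS)):
            raise ValidationError(f"strong learner requires weak set {WEAK_KINDS}")
        if self.meta.n_features != len(self.feature_names) + len(WEAK_KINDS):
            raise SchemaError("meta schema must equal base schema + 4 probability columns")

    @property
    def n_features(self) -> int:
        return len(self.feature_names)

    def _augment(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=np.float64)
        if X.ndim != 2 or X.shape[1] != self.n_features:
            raise SchemaError(
                f"expected {self.n_features} feature columns, got "
                f"{X.shape[1] if X.ndim == 2 else X.shape}"
            )
        cols = [self.weak[k].predict_proba(X) for k in WEAK_KINDS]
        return np.column_stack([X] + cols)

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        return self.meta.predict_proba(self._augment(X))


def train_classifier(
    spec: ClassifierSpec,
    X: np.ndarray,
    y: np.ndarray,
    feature_names: list[str] | None = None,
    schema_hash: str | None = None,
    iteration: int = 1,
) -> TrainedModel:
    """Fit one base classifier on the tagged-voxel table.

    Deterministic for a fixed ``spec.seed``; requires at least one sample
    of each class.
    """
    X, y = _validate_training_data(X, y)
    if feature_names is None:
        feature_names = [f"f{j}" for j in range(X.shape[1])]
    if len(feature_names) != X.shape[1]:
        raise SchemaError("feature_names length must match X columns")
    est = _build_estimator(spec)
    est.fit(X, y)
    return TrainedModel(
        spec=spec,
        estimator=est,
        schema_hash=schema_hash or _names_hash(feature_names),
        feature_names=list(feature_names),
        metadata={
            "n_tagged": int(X.shape[0]),
            "class_counts": {"negative": int((y == 0).sum()), "positive": int((y == 1).sum())},
            "iteration": int(iteration),
            "seed": int(spec.seed),
        },
    )


def _names_hash(names: list[str]) -> str:
    import hashlib

    return hashlib.sha256(json.dumps(list(names)).encode()).hexdigest()[:16]


def predict_proba(model: TrainedModel | StrongLearnerModel, X: np.ndarray) -> np.ndarray:
    """Positive-class probability for each row of ``X``."""
    return model.predict_proba(X)


def train_strong(
    X: np.ndarray,
    y: np.ndarray,
    seed: int = 0,
    feature_names: list[str] | None = None,
    schema_hash: str | None = None,
    iteration: int = 1,
    out_of_fold: bool = False,
    hyperparameters: dict | None = None,
) -> StrongLearnerModel:
    """Fit the stacked strong learner.

    The four weak learners (RFC, MLP, SVM, NBC) are trained on ``X``; their
    positive-class probabilities on the training voxels are appended as four
    extra columns and a gradient-boosting meta model is fitted on the
    augmented matrix.  With ``out_of_fold=True`` the appended training
    columns come from stratified 3-fold cross-fitting instead.
    """
    X, y = _validate_training_data(X, y)
    if feature_names is None:
        feature_names = [f"f{j}" for j in range(X.shape[1])]
    base_hash = schema_hash or _names_hash(feature_names)
    hp = hyperparameters or {}

    weak: dict[str, TrainedModel] = {}
    for kind in WEAK_KINDS:
        weak[kind] = train_classifier(
            ClassifierSpec(kind, hp.get(kind, {}), seed=seed),
            X,
            y,
            feature_names=feature_names,
            schema_hash=base_hash,
            iteration=iteration,
        )

    if out_of_fold and np.min(np.bincount(y)) >= 3:
        prob_cols = np.zeros((X.shape[0], len(WEAK_KINDS)))
        skf = StratifiedKFold(n_splits=3, shuffle=True, random_state=seed)
        for tr, te in skf.split(X, y):
            for j, kind in enumerate(WEAK_KINDS):
                fold = train_classifier(
                    ClassifierSpec(kind, hp.get(kind, {}), seed=seed), X[tr], y[tr]
                )
                prob_cols[te, j] = fold.predict_proba(X[te])
    else:
        prob_cols = np.column_stack([weak[k].predict_proba(X) for k in WEAK_KINDS])

    X_meta = np.column_stack([X, prob_cols])
    meta_names = list(feature_names) + [f"P_{k}" for k in WEAK_KINDS]
    meta = train_classifier(
        ClassifierSpec("XGB", hp.get("XGB", {}), seed=seed),
        X_meta,
        y,
        feature_names=meta_names,
        iteration=iteration,
    )
    return StrongLearnerModel(
        weak=weak,
        meta=meta,
        schema_hash=base_hash,
        feature_names=list(feature_names),
        metadata={
            "n_tagged": int(X.shape[0]),
            "class_counts": {"negative": int((y == 0).sum()), "positive": int((y == 1).sum())},
            "iteration": int(iteration),
            "seed": int(seed),
            "out_of_fold": bool(out_of_fold),
        },
    )


# ---------------------------------------------------------------------------
# persistence: zip archive with a JSON manifest + joblib blob

def save_model(model: TrainedModel | StrongLearnerModel, path) -> None:
    if isinstance(model, StrongLearnerModel):
        manifest = {
            "archive_version": _ARCHIVE_VERSION,
            "model_class": "strong",
            "schema_hash": model.schema_hash,
            "feature_names": model.feature_names,
            "metadata": model.metadata,
        }
    elif isinstance(model, TrainedModel):
        manifest = {
            "archive_version": _ARCHIVE_VERSION,
            "model_class": "base",
            "kind": model.spec.kind,
            "schema_hash": model.schema_hash,
            "feature_names": model.feature_names,
            "metadata": model.metadata,
        }
    else:
        raise ValidationError(f"cannot save object of type {type(model).__name__}")
    blob = io.BytesIO()
    joblib.dump(model, blob)
    with zipfile.ZipFile(path, "w", compression=zipfile.ZIP_DEFLATED) as zf:
        zf.writestr("manifest.json", json.dumps(manifest, indent=1))
        zf.writestr("model.joblib", blob.getvalue())


def load_model(path) -> TrainedModel | StrongLearnerModel:
    try:
        with zipfile.ZipFile(path) as zf:
            manifest = json.loads(zf.read("manifest.json"))
            blob = zf.read("model.joblib")
    except (zipfile.BadZipFile, KeyError, OSError, json.JSONDecodeError) as exc:
        raise FormatError(f"not a readable model archive: {path} ({exc})") from exc
    if manifest.get("archive_version") != _ARCHIVE_VERSION:
        raise FormatError(
            f"model archive version {manifest.get('archive_version')} unsupported"
        )
    model = joblib.load(io.BytesIO(blob))
    if manifest["schema_hash"] != model.schema_hash:
        raise FormatError("model archive manifest does not match its payload")
    return model


# ---------------------------------------------------------------------------
# feature importance

def feature_importance(model: TrainedModel) -> list[tuple[str, float]]:
    """Impurity-based feature importance as (name, percent), descending.

    Only tree ensembles (RFC, XGB) expose the reduction-in-impurity metric;
    the percentages are normalised to sum to 100.
    """
    if isinstance(model, StrongLearnerModel):
        raise ValidationError(
            "strong learner importance is ambiguous; inspect model.meta or a weak RFC"
        )
    if not isinstance(model, TrainedModel) or model.spec.kind not in ("RFC", "XGB"):
        kind = getattr(getattr(model, "spec", None), "kind", type(model).__name__)
        raise ValidationError(f"impurity importance unsupported for {kind}")
    imp = np.asarray(model.estimator.feature_importances_, dtype=np.float64)
    total = imp.sum()
    if total <= 0:
        raise ValidationError("model carries no importance signal")
    pct = 100.0 * imp / total
    order = np.argsort(pct)[::-1]
    return [(model.feature_names[i], float(pct[i])) for i in order]
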