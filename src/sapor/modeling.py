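"""Model zoo, cross-validation driver and evaluation metrics.

Five model families are trained on the cleaned descriptor table: logistic
regression, k-nearest neighbours, random forest, gradient boosting
(LightGBM) and a multi-layer perceptron (2 fully connected layers of 100
ReLU units, Adam optimizer).  Each family carries its own preprocessing
policy: winsorization everywhere; min-max scaling plus constant-1 imputation
for the scale-sensitive learners; constant -99999 imputation for the random
forest; native NaN routing for gradient boosting.

Evaluation uses stratified k-fold cross-validation, optionally repeated with
a different shuffle per repetition, scoring AUROC and AUPRC plus F1,
precision and recall at the 0.5 threshold.  Out-of-fold probabilities are
recorded so every compound has one held-out prediction per repetition.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lightgbm import LGBMClassifier
from sklearn import metrics as skm
from sklearn.impute import SimpleImputer
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import MinMaxScaler
from sklearn.ensemble import RandomForestClassifier

from .cleaning import NATIVE_MISSING, PreprocessPolicy, Winsorizer
from .descriptors import FeatureTable

__all__ = [
    "MODEL_FAMILIES",
    "CVSpec",
    "ModelSpec",
    "CVResult",
    "default_policy",
    "make_model",
    "stratified_fold_indices",
    "auroc",
    "auprc",
    "threshold_metrics",
    "run_cv",
]

MODEL_FAMILIES = ("logistic_regression", "knn", "random_forest", "gradient_boosting", "mlp")

_SCALED_FAMILIES = {"logistic_regression", "knn", "mlp"}


@dataclass
class CVSpec:
    """Stratified k-fold CV, repeated with a fresh shuffle each repetition."""

    k: int = 10
    repeats: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k < 2:
            raise ValueError("k must be >= 2")
        if self.repeats < 1:
            raise ValueError("repeats must be >= 1")


def default_policy(family: str) -> PreprocessPolicy:
    """Preprocessing defaults per model family."""
    if family in _SCALED_FAMILIES:
        return PreprocessPolicy(scale="minmax", impute_constant=1.0)
    if family == "random_forest":
        return PreprocessPolicy(scale="none", impute_constant=-99999.0)
    if family == "gradient_boosting":
        return PreprocessPolicy(scale="none", impute_constant=NATIVE_MISSING)
    raise ValueError(f"unknown family {family!r}; expected one of {MODEL_FAMILIES}")


@dataclass
class ModelSpec:
    """A model family plus hyperparameters and its preprocessing policy."""

    family: str
    hyperparams: dict = field(default_factory=dict)
    preprocess: PreprocessPolicy | None = None

    def __post_init__(self) -> None:
        if self.family not in MODEL_FAMILIES:
            raise ValueError(f"unknown family {self.family!r}; expected one of {MODEL_FAMILIES}")
        if self.preprocess is None:
            self.preprocess = default_policy(self.family)


def _make_estimator(spec: ModelSpec, random_state: int):
    hp = dict(spec.hyperparams)
    if spec.family == "logistic_regression":
        hp.setdefault("max_iter", 2000)
        return LogisticRegression(random_state=random_state, **hp)
    if spec.family == "knn":
        return KNeighborsClassifier(**hp)
    if spec.family == "random_forest":
        return RandomForestClassifier(random_state=random_state, **hp)
    if spec.family == "gradient_boosting":
        hp.setdefault("verbose", -1)
        return LGBMClassifier(random_state=random_state, **hp)
    if spec.family == "mlp":
        hp.setdefault("hidden_layer_sizes", (100, 100))
        hp.setdefault("activation", "relu")
        hp.setdefault("solver", "adam")
        hp.setdefault("max_iter", 300)
        return MLPClassifier(random_state=random_state, **hp)
    raise ValueError(spec.family)


def make_model(spec: ModelSpec, random_state: int = 0) -> Pipeline:
    """Build the preprocessing + learner pipeline for one model family.

    All preprocessing statistics (winsorization bounds, min-max ranges,
    imputation) are fitted inside the pipeline, hence on training folds only.
    """
    policy = spec.preprocess
    steps: list[tuple] = [("winsorize", Winsorizer(lo=policy.winsorize_lo, hi=policy.winsorize_hi))]
    if policy.scale == "minmax":
        steps.append(("scale", MinMaxScaler(clip=False)))
    if policy.impute_constant != NATIVE_MISSING:
        steps.append(
            ("impute", SimpleImputer(strategy="constant",
                                     fill_value=float(policy.impute_constant),
                                     keep_empty_features=True))
        )
    steps.append(("model", _make_estimator(spec, random_state)))
    return Pipeline(steps)


def stratified_fold_indices(targets, k: int, seed: int = 0) -> list[np.ndarray]:
    """Partition indices into k stratified folds (test-index sets)."""
    y = np.asarray(targets)
    classes, counts = np.unique(y, return_counts=True)
    if counts.min() < k:
        raise ValueError(
            f"smallest class has {counts.min()} members; cannot stratify into {k} folds"
        )
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    return [test for _, test in skf.split(np.zeros(len(y)), y)]


def auroc(scores, labels) -> float:
    """Area under the ROC curve == P(random positive outscores random
    negative), ties counted half (Mann–Whitney identity)."""
    y = np.asarray(labels)
    if len(np.unique(y)) < 2:
        raise ValueError("AUROC undefined: labels contain a single class")
    return float(skm.roc_auc_score(y, np.asarray(scores, dtype=float)))


def auprc(scores, labels) -> float:
    """Area under the precision-recall step curve (average-precision form)."""
    y = np.asarray(labels)
    if y.sum() == 0:
        raise ValueError("AUPRC undefined: no positive labels")
    return float(skm.average_precision_score(y, np.asarray(scores, dtype=float)))


def threshold_metrics(scores, labels, threshold: float = 0.5) -> dict[str, float]:
    """F1, precision and recall at a fixed probability threshold.

    With no predicted positives, precision is reported as 0 with a warning.
    """
    y = np.asarray(labels)
    pred = (np.asarray(scores, dtype=float) >= threshold).astype(int)
    if pred.sum() == 0:
        warnings.warn("no predicted positives at this threshold; precision reported as 0")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        precision = skm.precision_score(y, pred, zero_division=0)
        recall = skm.recall_score(y, pred, zero_division=0)
        f1 = skm.f1_score(y, pred, zero_division=0)
    return {"f1": float(f1), "precision": float(precision), "recall": float(recall)}


@dataclass
class CVResult:
    """Per-fold metrics plus out-of-fold probabilities, one row per (repeat, fold)."""

    per_fold: pd.DataFrame
    oof_predictions: np.ndarray  # shape (repeats, n_samples)
    k: int
    repeats: int
    seed: int
    models: list | None = None

    @property
    def auroc_scores(self) -> np.ndarray:
        return self.per_fold["auroc"].to_numpy()

    def summary(self) -> pd.DataFrame:
        """Mean with normal-approximation 95% CI across the k x repeats folds."""
        cols = ["auroc", "auprc", "f1", "precision", "recall"]
        rows = {}
        n = len(self.per_fold)
        for c in cols:
            v = self.per_fold[c].to_numpy()
            half = 1.959963984540054 * v.std(ddof=1) / np.sqrt(n) if n > 1 else 0.0
            rows[c] = {"mean": v.mean(), "ci_lo": v.mean() - half, "ci_hi": v.mean() + half}
        return pd.DataFrame(rows).T


def run_cv(
    table: FeatureTable,
    model: ModelSpec,
    cv: CVSpec,
    return_models: bool = False,
) -> CVResult:
    """Repeated stratified k-fold CV with leakage-free preprocessing.

    Per fold: fit the full pipeline (winsorization / scaling / imputation
    statistics included) on the training split only, score the held-out
    split.  Every learner with internal randomness is seeded
    ``cv.seed + repeat`` so each repetition reshuffles reproducibly.
    """
    X = table.X.to_numpy(dtype=float)
    y = table.y.to_numpy(dtype=int)
    n = len(y)
    records = []
    oof = np.full((cv.repeats, n), np.nan)
    fitted = [] if return_models else None
    for rep in range(cv.repeats):
        rep_seed = cv.seed + rep
        folds = stratified_fold_indices(y, cv.k, seed=rep_seed)
        for fold_id, test_idx in enumerate(folds):
            train_mask = np.ones(n, dtype=bool)
            train_mask[test_idx] = False
            pipe = make_model(model, random_state=rep_seed)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                pipe.fit(X[train_mask], y[train_mask])
                proba = pipe.predict_proba(X[test_idx])[:, 1]
            oof[rep, test_idx] = proba
            rec = {
                "repeat": rep,
                "fold": fold_id,
                "auroc": auroc(proba, y[test_idx]),
                "auprc": auprc(proba, y[test_idx]),
            }
            rec.update(threshold_metrics(proba, y[test_idx]))
            records.append(rec)
            if return_models:
                fitted.append(pipe)
    per_fold = pd.DataFrame.from_records(records)
    return CVResult(per_fold=per_fold, oof_predictions=oof,
                    k=cv.k, repeats=cv.repeats, seed=cv.seed, models=fitted)
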