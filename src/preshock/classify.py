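"""Imbalance-aware RBF-SVM training, tuning and validation.

The classifier is a soft-margin SVM (RBF kernel by default), tuned by grid
search over C and gamma with stratified inner cross-validation.  Class
imbalance — the clinical cohort has roughly 3.5 unsuccessful shocks per
successful one — is handled by inverse-frequency class weighting and/or
SMOTE oversampling of the minority class, both applied to training data
only.  Validation utilities cover stratified hold-out evaluation,
leave-one-subject-out cross-validation, hyperparameter sensitivity,
feature ablation and baseline model comparison.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from itertools import combinations

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import (
    accuracy_score,
    confusion_matrix,
    precision_recall_fscore_support,
    roc_auc_score,
)
from sklearn.model_selection import StratifiedKFold
from sklearn.neighbors import NearestNeighbors
from sklearn.svm import SVC

from .records import CODE_TO_LABEL

DEFAULT_C_GRID = (0.01, 0.1, 1.0, 10.0, 100.0, 1000.0)
DEFAULT_GAMMA_GRID = (0.01, 0.1, 1.0, 10.0, 100.0)


@dataclass(frozen=True)
class TrainConfig:
    """Training, tuning and imbalance-handling settings."""

    kernel: str = "rbf"
    c_grid: tuple = DEFAULT_C_GRID
    gamma_grid: tuple = DEFAULT_GAMMA_GRID
    split_ratio: float = 0.7
    imbalance: str = "both"  # none | class_weight | smote | both
    smote_k: int = 5
    inner_cv_folds: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kernel not in ("rbf", "linear"):
            raise ValueError("kernel must be 'rbf' or 'linear'")
        if not self.c_grid or not self.gamma_grid:
            raise ValueError("hyperparameter grids must be nonempty")
        if not 0 < self.split_ratio < 1:
            raise ValueError("split_ratio must be in (0, 1)")
        if self.imbalance not in ("none", "class_weight", "smote", "both"):
            raise ValueError(f"unknown imbalance mode {self.imbalance!r}")
        if self.smote_k < 1:
            raise ValueError("smote_k must be >= 1")
        if self.inner_cv_folds < 2:
            raise ValueError("inner_cv_folds must be >= 2")

    @property
    def use_class_weight(self) -> bool:
        return self.imbalance in ("class_weight", "both")

    @property
    def use_smote(self) -> bool:
        return self.imbalance in ("smote", "both")


@dataclass(frozen=True)
class Scaler:
    """Per-feature z-scoring statistics learned on training data only."""

    mean: np.ndarray
    sd: np.ndarray  # population SD; 0 for constant features
    constant_mask: np.ndarray

    def transform(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        sd = np.where(self.constant_mask, 1.0, self.sd)
        return (X - self.mean) / sd


def fit_scaler(X) -> Scaler:
    """Learn zero-mean / unit-variance statistics (population SD).

    Constant features are flagged and mapped to zero (with a warning).
    """
    X = np.asarray(X, dtype=float)
    if X.size == 0:
        raise ValueError("cannot fit a scaler on an empty matrix")
    mean = X.mean(axis=0)
    sd = X.std(axis=0)  # ddof=0
    constant = sd == 0
    if constant.any():
        warnings.warn(f"{int(constant.sum())} constant feature(s) map to zero")
    return Scaler(mean=mean, sd=sd, constant_mask=constant)


def apply_scaler(X, scaler: Scaler) -> np.ndarray:
    return scaler.transform(X)


def stratified_split(labels, ratio: float = 0.7, seed: int = 0):
    """Per-class shuffled split: round(ratio * class size) records to train.

    Rounding is to the nearest integer with ties to even, so a 251-record
    cohort with 195/56 class counts at ratio 0.7 allocates 136 and 39
    records to training.  Returns ``(train_idx, test_idx)``.
    """
    labels = np.asarray(labels)
    if not 0 < ratio < 1:
        raise ValueError("ratio must be in (0, 1)")
    rng = np.random.default_rng(seed)
    train, test = [], []
    for c in np.unique(labels):
        idx = np.flatnonzero(labels == c)
        if idx.size < 2:
            raise ValueError(f"class {c!r} has fewer than 2 members")
        idx = rng.permutation(idx)
        n_train = round(ratio * idx.size)
        train.extend(idx[:n_train])
        test.extend(idx[n_train:])
    return np.sort(np.asarray(train, dtype=int)), np.sort(np.asarray(test, dtype=int))


def smote(X, y, k: int = 5, seed: int = 0):
    """Synthetic minority oversampling to equal class counts.

    Each synthetic point is ``x + lam * (x_nn - x)`` with ``lam`` uniform
    on [0, 1), where ``x`` is a random minority sample and ``x_nn`` one of
    its ``k`` nearest minority neighbors (Euclidean).  Training-data-only
    by construction: callers pass the training fold.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    classes, counts = np.unique(y, return_counts=True)
    if classes.size != 2:
        raise ValueError("SMOTE expects exactly 2 classes")
    minority = classes[np.argmin(counts)]
    n_new = int(counts.max() - counts.min())
    if n_new == 0:
        return X.copy(), y.copy()
    X_min = X[y == minority]
    if X_min.shape[0] <= k:
        raise ValueError(
            f"minority class has {X_min.shape[0]} samples, needs > k={k}; lower k"
        )
    nn = NearestNeighbors(n_neighbors=k + 1).fit(X_min)  # self included
    _, neigh = nn.kneighbors(X_min)
    rng = np.random.default_rng(seed)
    base = rng.integers(0, X_min.shape[0], size=n_new)
    pick = rng.integers(1, k + 1, size=n_new)  # skip self at column 0
    lam = rng.random(n_new)
    x0 = X_min[base]
    x1 = X_min[neigh[base, pick]]
    synthetic = x0 + lam[:, None] * (x1 - x0)
    X_aug = np.vstack([X, synthetic])
    y_aug = np.concatenate([y, np.full(n_new, minority, dtype=y.dtype)])
    return X_aug, y_aug


def _class_weight(config: TrainConfig):
    return "balanced" if config.use_class_weight else None


def _make_svc(C: float, gamma: float, config: TrainConfig) -> SVC:
    return SVC(
        kernel=config.kernel,
        C=C,
        gamma=gamma if config.kernel == "rbf" else "scale",
        class_weight=_class_weight(config),
    )


def grid_search(X, y, config: TrainConfig) -> tuple[float, float]:
    """Best (C, gamma) by mean stratified inner-CV accuracy.

    Ties are broken toward smaller C then smaller gamma.  If the requested
    fold count would leave a fold without both classes, it is reduced with
    a warning.  SMOTE, when enabled, is re-applied inside each inner
    training fold so no synthetic point derives from validation data.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    min_class = int(np.unique(y, return_counts=True)[1].min())
    n_splits = min(config.inner_cv_folds, min_class)
    if n_splits < config.inner_cv_folds:
        warnings.warn(
            f"inner CV folds reduced {config.inner_cv_folds} -> {n_splits} "
            "to keep both classes in every fold"
        )
    if n_splits < 2:
        raise ValueError("too few samples per class for inner CV")
    skf = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=config.seed)
    folds = list(skf.split(X, y))

    best = None
    for C in sorted(config.c_grid):
        for gamma in sorted(config.gamma_grid):
            scores = []
            for f, (tr, va) in enumerate(folds):
                X_tr, y_tr = X[tr], y[tr]
                if config.use_smote:
                    try:
                        X_tr, y_tr = smote(X_tr, y_tr, k=config.smote_k,
                                           seed=config.seed + f)
                    except ValueError:
                        pass  # fold minority too small for k; train as-is
                model = _make_svc(C, gamma, config).fit(X_tr, y_tr)
                scores.append(accuracy_score(y[va], model.predict(X[va])))
            score = float(np.mean(scores))
            if best is None or score > best[0] + 1e-12:
                best = (score, C, gamma)
    return best[1], best[2]


@dataclass(frozen=True)
class SVMModel:
    """A fitted SVM with its hyperparameters and class-label map."""

    estimator: SVC
    C: float
    gamma: float
    label_names: dict = field(default_factory=lambda: dict(CODE_TO_LABEL))

    @property
    def classes(self) -> np.ndarray:
        return self.estimator.classes_

    def predict(self, X) -> np.ndarray:
        return self.estimator.predict(np.asarray(X, dtype=float))

    def decision_scores(self, X) -> np.ndarray:
        """Signed distance to the separating surface (positive class last)."""
        return self.estimator.decision_function(np.asarray(X, dtype=float))

    def dual_coefficients(self) -> tuple[np.ndarray, np.ndarray]:
        """(alpha_i * y_i, support vectors) for KKT inspection."""
        return self.estimator.dual_coef_[0], self.estimator.support_vectors_


def fit_svm(X, y, C: float, gamma: float, config: TrainConfig | None = None) -> SVMModel:
    """Fit the soft-margin SVM at fixed hyperparameters on scaled data."""
    config = config or TrainConfig()
    y = np.asarray(y)
    if np.unique(y).size < 2:
        raise ValueError("training data must contain both classes")
    est = _make_svc(C, gamma, config).fit(np.asarray(X, dtype=float), y)
    return SVMModel(estimator=est, C=C, gamma=gamma)


@dataclass(frozen=True)
class EvalReport:
    """Confusion matrix plus per-class and weighted metrics."""

    labels: np.ndarray  # class codes in confusion-matrix order
    confusion: np.ndarray
    per_class: dict  # code -> {precision, recall, f1, support}
    weighted: dict  # precision, recall, f1
    accuracy: float
    roc_auc: float | None

    def to_dict(self) -> dict:
        return {
            "labels": [int(c) for c in self.labels],
            "confusion": self.confusion.tolist(),
            "per_class": {
                str(code): {k: float(v) for k, v in m.items()}
                for code, m in self.per_class.items()
            },
            "weighted": {k: float(v) for k, v in self.weighted.items()},
            "accuracy": float(self.accuracy),
            "roc_auc": None if self.roc_auc is None else float(self.roc_auc),
        }


def f1_from_precision_recall(precision: float, recall: float) -> float:
    """Harmonic mean of precision and recall."""
    if precision + recall == 0:
        return 0.0
    return 2 * precision * recall / (precision + recall)


def evaluate(y_true, y_pred, scores=None, labels=None) -> EvalReport:
    """Full evaluation report from labels (and optional decision scores).

    ``scores`` are continuous decision values for the *largest* class code
    (the ROEA convention: code 2 is the positive class); ROC-AUC is
    omitted when they are not provided or only one class is present.
    """
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred must have equal length")
    if labels is None:
        labels = np.unique(y_true)
    labels = np.asarray(labels)
    unseen = set(np.unique(y_pred)) - set(labels.tolist())
    if unseen:
        raise ValueError(f"predictions contain unseen label values {sorted(unseen)}")

    cm = confusion_matrix(y_true, y_pred, labels=labels)
    prec, rec, f1, support = precision_recall_fscore_support(
        y_true, y_pred, labels=labels, zero_division=0
    )
    w_prec, w_rec, w_f1, _ = precision_recall_fscore_support(
        y_true, y_pred, labels=labels, average="weighted", zero_division=0
    )
    auc = None
    if scores is not None and np.unique(y_true).size == 2:
        auc = float(roc_auc_score(y_true == labels.max(), np.asarray(scores, float)))
    per_class = {
        int(c): {
            "precision": float(p),
            "recall": float(r),
            "f1": float(f),
            "support": int(s),
        }
        for c, p, r, f, s in zip(labels, prec, rec, f1, support)
    }
    return EvalReport(
        labels=labels,
        confusion=cm,
        per_class=per_class,
        weighted={"precision": float(w_prec), "recall": float(w_rec), "f1": float(w_f1)},
        accuracy=float(accuracy_score(y_true, y_pred)),
        roc_auc=auc,
    )


def train_and_evaluate(X, y, config: TrainConfig | None = None):
    """The full hold-out experiment: split, scale, rebalance, tune, fit, score.

    Returns ``(model, report, details)`` where ``details`` carries the
    train/test indices, scaler statistics and chosen hyperparameters —
    everything needed to audit that no test information leaked into
    training.
    """
    config = config or TrainConfig()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    train_idx, test_idx = stratified_split(y, config.split_ratio, config.seed)
    X_train, y_train = X[train_idx], y[train_idx]
    X_test, y_test = X[test_idx], y[test_idx]

    scaler = fit_scaler(X_train)
    X_train_s = scaler.transform(X_train)
    X_test_s = scaler.transform(X_test)

    C, gamma = grid_search(X_train_s, y_train, config)
    X_fit, y_fit = X_train_s, y_train
    if config.use_smote:
        X_fit, y_fit = smote(X_fit, y_fit, k=config.smote_k, seed=config.seed)
    model = fit_svm(X_fit, y_fit, C, gamma, config)

    report = evaluate(y_test, model.predict(X_test_s),
                      scores=model.decision_scores(X_test_s), labels=np.unique(y))
    details = {
        "train_idx": train_idx,
        "test_idx": test_idx,
        "scaler": scaler,
        "C": C,
        "gamma": gamma,
        "n_train_after_rebalance": int(np.asarray(y_fit).size),
    }
    return model, report, details


def loso_cv(X, y, config: TrainConfig | None = None):
    """Leave-one-subject-out cross-validation.

    One fold per record; scaler, SMOTE and grid search are re-fit inside
    every fold so the held-out record never influences training.  Returns
    ``(correct_flags, pooled_report)``.
    """
    config = config or TrainConfig()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    n = y.size
    if n < 3:
        raise ValueError("LOSO needs at least 3 records")
    preds = np.empty(n, dtype=y.dtype)
    scores = np.empty(n, dtype=float)
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        X_tr, y_tr = X[mask], y[mask]
        scaler = fit_scaler(X_tr)
        X_tr_s = scaler.transform(X_tr)
        C, gamma = grid_search(X_tr_s, y_tr, replace(config, seed=config.seed + i))
        X_fit, y_fit = X_tr_s, y_tr
        if config.use_smote:
            try:
                X_fit, y_fit = smote(X_fit, y_fit, k=config.smote_k, seed=config.seed + i)
            except ValueError:
                pass
        model = fit_svm(X_fit, y_fit, C, gamma, config)
        x_i = scaler.transform(X[i : i + 1])
        preds[i] = model.predict(x_i)[0]
        scores[i] = model.decision_scores(x_i)[0]
    correct = (preds == y).astype(float)
    pooled = evaluate(y, preds, scores=scores, labels=np.unique(y))
    return correct, pooled


def sensitivity(
    X_train, y_train, X_test, y_test,
    C: float, gamma: float,
    config: TrainConfig | None = None,
    perturbation: float = 0.10,
) -> float:
    """Max |accuracy deviation| when C and gamma vary within +/-perturbation.

    Inputs are assumed already scaled; the baseline model at (C, gamma) is
    refit at every point of the {1-p, 1, 1+p}^2 grid.
    """
    config = config or TrainConfig()
    baseline = fit_svm(X_train, y_train, C, gamma, config)
    base_acc = accuracy_score(y_test, baseline.predict(X_test))
    deviation = 0.0
    for fc in (1 - perturbation, 1.0, 1 + perturbation):
        for fg in (1 - perturbation, 1.0, 1 + perturbation):
            model = fit_svm(X_train, y_train, C * fc, gamma * fg, config)
            acc = accuracy_score(y_test, model.predict(X_test))
            deviation = max(deviation, abs(acc - base_acc))
    return float(deviation)


def default_ablation_subsets(feature_names) -> list[tuple[str, tuple[str, ...]]]:
    """Full set, each leave-one-out set, and each pair (7 rows for 3 features).

    For three features every leave-one-out subset coincides with a pair;
    both rows are kept so the table mirrors the conventional ablation
    layout (full / without-X / pairwise).
    """
    names = tuple(feature_names)
    subsets: list[tuple[str, tuple[str, ...]]] = [("all", names)]
    for name in names:
        rest = tuple(n for n in names if n != name)
        subsets.append((f"without_{name}", rest))
    for pair in combinations(names, 2):
        subsets.append(("+".join(pair), pair))
    return subsets


def ablation(
    feature_table: pd.DataFrame,
    y,
    subsets=None,
    config: TrainConfig | None = None,
) -> pd.DataFrame:
    """Re-run the full hold-out experiment on feature subsets.

    Returns one row per subset with accuracy and weighted metrics; the
    same seed is used throughout so the ``all`` row equals a direct run.
    """
    config = config or TrainConfig()
    if subsets is None:
        subsets = default_ablation_subsets(feature_table.columns)
    if not subsets:
        raise ValueError("subsets must be nonempty")
    rows = []
    for name, cols in subsets:
        cols = tuple(cols)
        if not cols:
            raise ValueError(f"subset {name!r} is empty")
        _, report, _ = train_and_evaluate(feature_table[list(cols)].to_numpy(), y, config)
        rows.append(
            {
                "configuration": name,
                "n_features": len(cols),
                "accuracy": report.accuracy,
                "weighted_precision": report.weighted["precision"],
                "weighted_recall": report.weighted["recall"],
                "weighted_f1": report.weighted["f1"],
            }
        )
    return pd.DataFrame(rows).set_index("configuration")


def compare_classifiers(
    feature_table: pd.DataFrame, y, config: TrainConfig | None = None
) -> pd.DataFrame:
    """SVM vs. random forest vs. logistic regression on one shared split.

    Every model sees the same scaled train/test data and a comparable
    small tuning budget (stratified inner CV); rows report accuracy and
    support-weighted precision/recall/F1.
    """
    config = config or TrainConfig()
    X = feature_table.to_numpy(dtype=float)
    y = np.asarray(y)
    train_idx, test_idx = stratified_split(y, config.split_ratio, config.seed)
    scaler = fit_scaler(X[train_idx])
    X_train, X_test = scaler.transform(X[train_idx]), scaler.transform(X[test_idx])
    y_train, y_test = y[train_idx], y[test_idx]

    def tune(factory, grid):
        min_class = int(np.unique(y_train, return_counts=True)[1].min())
        skf = StratifiedKFold(
            n_splits=min(config.inner_cv_folds, min_class),
            shuffle=True,
            random_state=config.seed,
        )
        folds = list(skf.split(X_train, y_train))
        best = None
        for params in grid:
            scores = [
                accuracy_score(
                    y_train[va], factory(**params).fit(X_train[tr], y_train[tr]).predict(X_train[va])
                )
                for tr, va in folds
            ]
            score = float(np.mean(scores))
            if best is None or score > best[0] + 1e-12:
                best = (score, params)
        return best[1]

    rows = {}

    # SVM through the package's own path
    C, gamma = grid_search(X_train, y_train, config)
    X_fit, y_fit = X_train, y_train
    if config.use_smote:
        X_fit, y_fit = smote(X_fit, y_fit, k=config.smote_k, seed=config.seed)
    svm_model = fit_svm(X_fit, y_fit, C, gamma, config)
    rows["svm"] = evaluate(y_test, svm_model.predict(X_test),
                           scores=svm_model.decision_scores(X_test), labels=np.unique(y))

    cw = _class_weight(config)
    rf_params = tune(
        lambda n_estimators, max_depth: RandomForestClassifier(
            n_estimators=n_estimators, max_depth=max_depth,
            class_weight=cw, random_state=config.seed,
        ),
        [{"n_estimators": n, "max_depth": d} for n in (100, 300) for d in (None, 10)],
    )
    rf = RandomForestClassifier(class_weight=cw, random_state=config.seed, **rf_params)
    rf.fit(X_fit, y_fit)
    rows["random_forest"] = evaluate(
        y_test, rf.predict(X_test),
        scores=rf.predict_proba(X_test)[:, -1], labels=np.unique(y),
    )

    lr_params = tune(
        lambda C: LogisticRegression(C=C, class_weight=cw, max_iter=2000),
        [{"C": c} for c in (0.01, 0.1, 1.0, 10.0, 100.0)],
    )
    lr = LogisticRegression(class_weight=cw, max_iter=2000, **lr_params)
    lr.fit(X_fit, y_fit)
    rows["logistic_regression"] = evaluate(
        y_test, lr.predict(X_test),
        scores=lr.decision_function(X_test), labels=np.unique(y),
    )

    return pd.DataFrame(
        {
            name: {
                "accuracy": r.accuracy,
                "weighted_precision": r.weighted["precision"],
                "weighted_recall": r.weighted["recall"],
                "weighted_f1": r.weighted["f1"],
                "roc_auc": r.roc_auc,
            }
            for name, r in rows.items()
        }
    ).T
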