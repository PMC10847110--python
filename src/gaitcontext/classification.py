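"""Indoor/outdoor context classification of walking periods.

Protocol: two ensemble learners — a Random Forest (40 trees, bootstrapped)
and a bagged SVM (60 RBF-kernel estimators) — are trained on the
biomechanics feature table with leave-one-participant-out (LOPO)
validation over the training pool: each fold fits on all pool participants
but one and is validated on the held-out participant, so reported metrics
measure generalization to unseen people. The best *case*
(algorithm x feature set, by average validation metrics) supplies its
per-fold models to the held-out test participants, where the single best
fold model is chosen for labeling the remaining (mixed / unlabeled)
periods. Class imbalance (~80% indoor) is handled by the ensembles
themselves; indoor is the positive class for F1.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.ensemble import BaggingClassifier, RandomForestClassifier
from sklearn.inspection import permutation_importance as _sk_permutation
from sklearn.metrics import accuracy_score, f1_score, roc_auc_score
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .config import ClassifierConfig
from .features import FEATURE_COLUMNS

logger = logging.getLogger(__name__)

ALGORITHMS = ("ensemble_svm", "random_forest")


class LeakageError(RuntimeError):
    """A participant appears on both sides of a train/test split."""


@dataclass(frozen=True)
class MetricsReport:
    accuracy: float
    f1: float
    auroc: float | None
    tp: int
    fp: int
    tn: int
    fn: int

    def as_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "f1": self.f1,
            "auroc": self.auroc,
            "tp": self.tp, "fp": self.fp, "tn": self.tn, "fn": self.fn,
        }


@dataclass
class FoldResult:
    held_out: str
    model: object
    metrics: MetricsReport


@dataclass
class ModelBundle:
    """Per-fold LOPO models plus their validation metrics."""

    algorithm: str
    feature_set: str
    folds: list[FoldResult]

    @property
    def avg_accuracy(self) -> float:
        return float(np.mean([f.metrics.accuracy for f in self.folds]))

    @property
    def avg_f1(self) -> float:
        return float(np.mean([f.metrics.f1 for f in self.folds]))

    @property
    def avg_auroc(self) -> float:
        vals = [f.metrics.auroc for f in self.folds if f.metrics.auroc is not None]
        return float(np.mean(vals)) if vals else float("nan")

    def summary(self) -> dict:
        return {
            "algorithm": self.algorithm,
            "feature_set": self.feature_set,
            "avg_accuracy": self.avg_accuracy,
            "avg_f1": self.avg_f1,
            "avg_auroc": self.avg_auroc,
            "folds": {
                f.held_out: f.metrics.as_dict() for f in self.folds
            },
        }


def _seed_int(seed: int, *stream: int) -> int:
    return int(np.random.SeedSequence([seed, *stream]).generate_state(1)[0]
               % (2**31 - 1))


class _ScaledSVC(BaseEstimator, ClassifierMixin):
    """Standardized RBF-kernel SVC that tolerates single-class bootstrap
    resamples (rare outdoor rows can vanish from a bagging draw): a
    degenerate fit predicts its only class with a saturated decision value
    oriented by the alphabetical class order BaggingClassifier uses."""

    def __init__(self, kernel: str = "rbf"):
        self.kernel = kernel

    def fit(self, X, y):
        self.classes_ = np.unique(y)
        if self.classes_.size < 2:
            self._pipe_ = None
            self._constant_ = self.classes_[0]
            return self
        self._pipe_ = make_pipeline(StandardScaler(), SVC(kernel=self.kernel))
        self._pipe_.fit(X, y)
        self.classes_ = self._pipe_[-1].classes_
        self._constant_ = None
        return self

    def predict(self, X):
        if self._pipe_ is None:
            return np.full(len(X), self._constant_, dtype=object)
        return self._pipe_.predict(X)

    def decision_function(self, X):
        if self._pipe_ is None:
            # positive favours the alphabetically later class
            sign = 1.0 if str(self._constant_) >= "outdoor" else -1.0
            return np.full(len(X), sign)
        return self._pipe_.decision_function(X)


def make_classifier(algorithm: str, config: ClassifierConfig | None = None,
                    seed: int = 0):
    """Instantiate one of the two ensemble learners with the fixed
    grid-search-winning hyperparameters."""
    cfg = config or ClassifierConfig()
    if algorithm == "random_forest":
        return RandomForestClassifier(
            n_estimators=cfg.rf_n_estimators, bootstrap=True,
            random_state=seed,
        )
    if algorithm == "ensemble_svm":
        return BaggingClassifier(
            estimator=_ScaledSVC(kernel=cfg.svm_kernel),
            n_estimators=cfg.svm_n_estimators,
            random_state=seed,
        )
    raise ValueError(f"unknown algorithm {algorithm!r}; choose from {ALGORITHMS}")


def indoor_score(model, X: np.ndarray, positive: str = "indoor") -> np.ndarray:
    """Continuous score in [0, 1] for the positive (indoor) class.

    Random forests report the averaged tree class-vote fraction; the bagged
    SVM reports the mean decision-function value across estimators, min-max
    mapped to [0, 1] within the evaluation set.
    """
    classes = list(model.classes_)
    if hasattr(model, "predict_proba") and not isinstance(model,
                                                          BaggingClassifier):
        return model.predict_proba(X)[:, classes.index(positive)]
    d = model.decision_function(X)
    span = d.max() - d.min()
    scaled = (d - d.min()) / span if span > 0 else np.full_like(d, 0.5)
    # decision_function > 0 favours classes_[1]
    return scaled if classes.index(positive) == 1 else 1.0 - scaled


def compute_metrics(y_true, y_pred, scores=None,
                    positive: str = "indoor") -> MetricsReport:
    """Accuracy, F1 (indoor positive), AUROC, and confusion counts.

    AUROC is None when the evaluation set contains a single class.
    """
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    pos_t = y_true == positive
    pos_p = y_pred == positive
    tp = int(np.sum(pos_t & pos_p))
    fp = int(np.sum(~pos_t & pos_p))
    tn = int(np.sum(~pos_t & ~pos_p))
    fn = int(np.sum(pos_t & ~pos_p))
    auroc = None
    if scores is not None and len(np.unique(y_true)) == 2:
        auroc = float(roc_auc_score(pos_t.astype(int), scores))
    return MetricsReport(
        accuracy=float(accuracy_score(y_true, y_pred)),
        f1=float(f1_score(y_true, y_pred, pos_label=positive,
                          zero_division=0)),
        auroc=auroc,
        tp=tp, fp=fp, tn=tn, fn=fn,
    )


def _xy(table: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    missing = [c for c in FEATURE_COLUMNS if c not in table.columns]
    if missing:
        raise KeyError(f"feature table missing columns: {missing}")
    return table[FEATURE_COLUMNS].to_numpy(), table["label"].to_numpy()


def pure_context_rows(table: pd.DataFrame) -> pd.DataFrame:
    """Rows labeled exclusively indoor or outdoor (training material)."""
    return table[table["label"].isin(["indoor", "outdoor"])]


def train_lopo(table: pd.DataFrame, algorithm: str,
               config: ClassifierConfig | None = None, seed: int = 0,
               feature_set: str = "biomechanics") -> ModelBundle:
    """Leave-one-participant-out training and validation.

    ``table`` is a feature table restricted to the training pool; rows
    labeled mixed or unlabeled are dropped. One fold per participant:
    fit on all others, validate on the held-out one. A fold whose held-out
    participant has a single class gets no AUROC (logged, excluded from
    the bundle average).
    """
    cfg = config or ClassifierConfig()
    data = pure_context_rows(table)
    pool = sorted(data["participant_id"].unique())
    if len(pool) < 2:
        raise ValueError("LOPO needs at least 2 participants with labeled data")
    if len(data["label"].unique()) < 2:
        raise ValueError("training pool must contain both classes")

    folds = []
    for i, held in enumerate(pool):
        train = data[data["participant_id"] != held]
        valid = data[data["participant_id"] == held]
        assert held not in set(train["participant_id"]), "leakage"
        if train["label"].nunique() < 2:
            # can happen in very small cohorts; an untrainable fold is
            # skipped rather than aborting the whole protocol
            logger.warning("fold %s: training set has a single class; "
                           "fold skipped", held)
            continue
        model = make_classifier(algorithm, cfg, seed=_seed_int(seed, i))
        X_tr, y_tr = _xy(train)
        model.fit(X_tr, y_tr)
        X_va, y_va = _xy(valid)
        scores = indoor_score(model, X_va, cfg.positive_label)
        metrics = compute_metrics(y_va, model.predict(X_va), scores,
                                  cfg.positive_label)
        if metrics.auroc is None:
            logger.info("fold %s: single-class validation set, AUROC undefined",
                        held)
        folds.append(FoldResult(held, model, metrics))
    if not folds:
        raise ValueError("no trainable LOPO folds (every training split "
                         "was single-class)")
    return ModelBundle(algorithm, feature_set, folds)


def select_case(bundles: list[ModelBundle]) -> ModelBundle:
    """Choose the best case (algorithm x feature set) by the unweighted
    mean of average accuracy, F1, and AUROC; ties break by accuracy, then
    F1, then algorithm id."""
    if not bundles:
        raise ValueError("no bundles to select from")

    def key(b: ModelBundle):
        auroc = b.avg_auroc
        combined = np.nanmean([b.avg_accuracy, b.avg_f1, auroc])
        # lexicographic: higher combined, higher accuracy, higher F1,
        # then *lower* algorithm id
        return (-combined, -b.avg_accuracy, -b.avg_f1, b.algorithm,
                b.feature_set)

    return min(bundles, key=key)


def select_model(bundle: ModelBundle, test_table: pd.DataFrame,
                 config: ClassifierConfig | None = None
                 ) -> tuple[FoldResult, MetricsReport, pd.DataFrame]:
    """Evaluate every fold model of the chosen case on the held-out test
    participants and return the best (highest accuracy; ties by F1, then
    AUROC, then fold id), its test metrics, and the per-model metric table.

    Raises
    ------
    LeakageError
        If any test participant was part of the bundle's training pool.
    """
    cfg = config or ClassifierConfig()
    data = pure_context_rows(test_table)
    pool = {f.held_out for f in bundle.folds}
    overlap = pool & set(data["participant_id"].unique())
    if overlap:
        raise LeakageError(
            f"test participants overlap the training pool: {sorted(overlap)}")

    X, y = _xy(data)
    rows = []
    results = []
    for fold in bundle.folds:
        scores = indoor_score(fold.model, X, cfg.positive_label)
        m = compute_metrics(y, fold.model.predict(X), scores,
                            cfg.positive_label)
        results.append((fold, m))
        rows.append({"fold": fold.held_out, "accuracy": m.accuracy,
                     "f1": m.f1, "auroc": m.auroc})

    def key(item):
        fold, m = item
        auroc = m.auroc if m.auroc is not None else -1.0
        return (-m.accuracy, -m.f1, -auroc, fold.held_out)

    best_fold, best_metrics = min(results, key=key)
    return best_fold, best_metrics, pd.DataFrame(rows)


def permutation_importance(model, table: pd.DataFrame, n_repeats: int = 20,
                           seed: int = 0,
                           feature_columns: list[str] | None = None
                           ) -> pd.DataFrame:
    """Mean ± SD decrease in accuracy when one feature column is shuffled.

    Columns not informative to the model score ~0; the dominant feature
    scores highest. Requires at least 20 rows for a stable estimate.
    """
    cols = feature_columns or FEATURE_COLUMNS
    if len(table) < 20:
        raise ValueError("permutation importance needs at least 20 rows")
    X = table[cols].to_numpy()
    y = table["label"].to_numpy()
    res = _sk_permutation(model, X, y, scoring="accuracy",
                          n_repeats=n_repeats, random_state=seed)
    return pd.DataFrame(
        {
            "feature": cols,
            "importance_mean": res.importances_mean,
            "importance_sd": res.importances_std,
        }
    ).sort_values("importance_mean", ascending=False, ignore_index=True)


def classify(model, table: pd.DataFrame,
             config: ClassifierConfig | None = None) -> pd.DataFrame:
    """Predict context for each row; returns the table with
    ``predicted_label`` (indoor/outdoor) and ``score_indoor`` in [0, 1].

    Raises
    ------
    KeyError
        If a feature column is missing.
    """
    cfg = config or ClassifierConfig()
    missing = [c for c in FEATURE_COLUMNS if c not in table.columns]
    if missing:
        raise KeyError(f"feature table missing columns: {missing}")
    X = table[FEATURE_COLUMNS].to_numpy()
    out = table.copy()
    out["predicted_label"] = model.predict(X)
    out["score_indoor"] = indoor_score(model, X, cfg.positive_label)
    return out
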