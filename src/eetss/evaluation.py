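"""Classification and comparison protocol.

Signature (or baseline) features are min-max scaled with a scaler fit
on the training split only, reduced by recursive feature elimination
(linear maximum-margin estimator, one feature dropped per step), and
fed to a bank of six classifiers (SVM, RF, KNN, NB, LR, XGB) tuned by
exhaustive grid search with 5-fold stratified cross-validation refit on
recall.  The whole pipeline is repeated over 30 stratified 80:20
train/test splits with seeds 0..29; the primary metric is recall of the
positive (disease) class, with rank-based AUC recorded as a bias check
and Welch's unequal-variance t-test used to compare methods.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.feature_selection import RFE
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import GridSearchCV, StratifiedKFold, train_test_split
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.ensemble import RandomForestClassifier
from sklearn.preprocessing import MinMaxScaler
from sklearn.svm import SVC

from .signatures import SignatureMatrix

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------

def recall_score(true_labels, predicted_labels, positive_label) -> float:
    """Recall of the positive class: TP / (TP + FN).

    Errors if the truth contains no positive instance (the ratio is
    undefined).
    """
    t = np.asarray(true_labels)
    p = np.asarray(predicted_labels)
    if t.shape != p.shape:
        raise ValueError("label arrays must be aligned")
    pos = t == type(t.flat[0])(positive_label)
    if not pos.any():
        raise ValueError("no positive instances in the truth: recall undefined")
    tp = int((p[pos] == t[pos]).sum())
    return tp / int(pos.sum())


def auc_score(true_labels, scores, positive_label) -> float:
    """Rank-based AUC with tie correction (Mann-Whitney U / (n+ * n-))."""
    t = np.asarray(true_labels)
    s = np.asarray(scores, dtype=float)
    pos = t == type(t.flat[0])(positive_label)
    n_pos, n_neg = int(pos.sum()), int((~pos).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC needs both classes present in the truth")
    ranks = stats.rankdata(s)
    u = ranks[pos].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def welch_compare(metric_a, metric_b) -> float:
    """Two-sided Welch (unequal-variance) t-test p-value between two
    per-seed metric samples."""
    a = np.asarray(metric_a, dtype=float)
    b = np.asarray(metric_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("empty metric sample")
    if np.var(a) == 0 and np.var(b) == 0:
        if np.mean(a) == np.mean(b):
            return 1.0
        raise ValueError("both samples have zero variance with unequal means")
    return float(stats.ttest_ind(a, b, equal_var=False).pvalue)


# ---------------------------------------------------------------------------
# Classifier bank
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ClassifierSpec:
    """A named classifier plus its hyperparameter search grid."""

    name: str
    grid: dict

    def build(self, seed: int):
        """Instantiate the estimator for one protocol seed."""
        if self.name == "SVM":
            return SVC(random_state=seed)
        if self.name == "RF":
            return RandomForestClassifier(random_state=seed)
        if self.name == "KNN":
            return KNeighborsClassifier()
        if self.name == "NB":
            return GaussianNB()
        if self.name == "LR":
            return LogisticRegression(max_iter=2000, random_state=seed)
        if self.name == "XGB":
            from xgboost import XGBClassifier

            return XGBClassifier(
                random_state=seed,
                eval_metric="logloss",
                verbosity=0,
                n_jobs=1,
            )
        raise ValueError(f"unknown classifier {self.name!r}")


def default_classifier_bank() -> list[ClassifierSpec]:
    """The six-classifier bank with its standard hyperparameter grids."""
    return [
        ClassifierSpec("SVM", {"kernel": ["linear", "poly", "rbf"],
                               "C": [1, 10], "degree": [2, 3]}),
        ClassifierSpec("RF", {"n_estimators": [10, 100, 500],
                              "criterion": ["gini", "entropy"]}),
        ClassifierSpec("KNN", {"n_neighbors": [1, 3, 5],
                               "weights": ["uniform", "distance"]}),
        ClassifierSpec("NB", {"var_smoothing": [1e-9, 1e-8, 1e-7, 1e-6, 1e-5]}),
        # l2 penalty throughout (sklearn's default; listing it explicitly is
        # deprecated in recent sklearn)
        ClassifierSpec("LR", {"solver": ["newton-cg", "lbfgs", "liblinear"],
                              "C": [100, 10, 1.0, 0.1, 0.01]}),
        ClassifierSpec("XGB", {"n_estimators": [100], "learning_rate": [0.3],
                               "max_depth": [6], "colsample_bytree": [1.0],
                               "subsample": [1.0]}),
    ]


def reduced_classifier_bank() -> list[ClassifierSpec]:
    """A lighter bank for simulation studies: linear SVM, LR and NB with
    trimmed grids (same protocol, lower cost)."""
    return [
        ClassifierSpec("SVM", {"kernel": ["linear"], "C": [1, 10]}),
        ClassifierSpec("LR", {"solver": ["lbfgs"], "C": [10, 1.0, 0.1]}),
        ClassifierSpec("NB", {"var_smoothing": [1e-9, 1e-7, 1e-5]}),
    ]


# ---------------------------------------------------------------------------
# Protocol
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SplitProtocol:
    """Repeated stratified train/test evaluation settings."""

    n_repeats: int = 30
    test_fraction: float = 0.2
    cv_folds: int = 5
    rfe_fraction: float = 0.5
    seeds: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        if not self.seeds:
            object.__setattr__(self, "seeds", tuple(range(self.n_repeats)))


@dataclass
class SeedResult:
    seed: int
    classifier: str
    recall: float
    auc: float
    tp: int
    fn: int
    params: dict


@dataclass
class EvaluationReport:
    """Per-seed, per-classifier results plus aggregates."""

    results: list[SeedResult]
    mean_recall: dict[str, float]
    mean_auc: dict[str, float]
    best_classifier: str
    welch_pvalues: dict[str, float] = field(default_factory=dict)

    def metric_series(self, classifier: str, metric: str = "recall") -> np.ndarray:
        vals = [getattr(r, metric) for r in self.results if r.classifier == classifier]
        return np.array(vals)

    def to_dict(self) -> dict:
        return {
            "per_seed": [
                {"seed": r.seed, "classifier": r.classifier, "recall": r.recall,
                 "auc": r.auc, "tp": r.tp, "fn": r.fn,
                 "params": {k: _jsonable(v) for k, v in r.params.items()}}
                for r in self.results
            ],
            "mean_recall": self.mean_recall,
            "mean_auc": self.mean_auc,
            "best_classifier": self.best_classifier,
            "welch_pvalues": self.welch_pvalues,
        }


def _jsonable(v):
    if isinstance(v, (np.integer,)):
        return int(v)
    if isinstance(v, (np.floating,)):
        return float(v)
    return v


def preprocess_features(
    train: np.ndarray, test: np.ndarray
) -> tuple[np.ndarray, np.ndarray, MinMaxScaler]:
    """Min-max scale both splits with a scaler fit on the train split only.

    Test values outside the training range are not clipped (they map
    outside [0, 1]); constant training columns map to 0 with a warning.
    """
    scaler = MinMaxScaler(clip=False)
    scaler.fit(train)
    constant = scaler.data_range_ == 0
    if constant.any():
        logger.warning("%d constant training column(s) map to 0", int(constant.sum()))
    return scaler.transform(train), scaler.transform(test), scaler


def rfe_select(
    train: np.ndarray, labels: np.ndarray, n_keep: int | None = None
) -> np.ndarray:
    """Recursive feature elimination on the training split.

    One feature is dropped per step, ranked by the coefficient
    magnitudes of a linear maximum-margin classifier (C = 1).  Returns
    a boolean column mask.  Default ``n_keep`` is half the columns,
    rounded up.
    """
    n_cols = train.shape[1]
    if n_keep is None:
        n_keep = math.ceil(n_cols / 2)
    if n_keep < 1:
        raise ValueError(f"n_keep must be >= 1, got {n_keep}")
    if n_keep > n_cols:
        raise ValueError(f"n_keep {n_keep} > column count {n_cols}")
    if n_keep == n_cols:
        return np.ones(n_cols, dtype=bool)
    rfe = RFE(SVC(kernel="linear", C=1.0), n_features_to_select=n_keep, step=1)
    rfe.fit(train, labels)
    return rfe.support_


def _positive_scores(estimator, x: np.ndarray) -> np.ndarray:
    """Continuous score for the positive (encoded 1) class."""
    if hasattr(estimator, "predict_proba"):
        proba = estimator.predict_proba(x)
        idx = int(np.where(estimator.classes_ == 1)[0][0])
        return proba[:, idx]
    margin = estimator.decision_function(x)
    return margin if estimator.classes_[1] == 1 else -margin


def evaluate_protocol(
    matrix: SignatureMatrix,
    specs: list[ClassifierSpec] | None = None,
    protocol: SplitProtocol | None = None,
    rfe_n_keep: int | None = None,
) -> EvaluationReport:
    """Run the repeated-split evaluation protocol on a feature matrix.

    For each seed: stratified 80:20 split, train-only min-max scaling,
    RFE, then per classifier an exhaustive grid search with stratified
    5-fold cross-validation refit on recall; test recall and AUC are
    recorded.  The best classifier has the highest mean recall (ties
    broken by mean AUC).
    """
    if specs is None:
        specs = default_classifier_bank()
    if protocol is None:
        protocol = SplitProtocol()
    y_all = np.asarray(
        [1 if l == matrix.positive_label else 0 for l in matrix.labels], dtype=int
    )
    if min((y_all == 1).sum(), (y_all == 0).sum()) < 2:
        raise ValueError("need >= 2 instances per class")
    x_all = matrix.features

    results: list[SeedResult] = []
    for seed in protocol.seeds:
        x_tr, x_te, y_tr, y_te = train_test_split(
            x_all, y_all,
            test_size=protocol.test_fraction,
            random_state=seed,
            stratify=y_all,
        )
        if y_te.sum() == 0 or y_tr.sum() == 0:
            raise RuntimeError(f"seed {seed}: a split lost the positive class")
        x_tr_s, x_te_s, _ = preprocess_features(x_tr, x_te)
        mask = rfe_select(x_tr_s, y_tr, n_keep=rfe_n_keep)
        x_tr_s, x_te_s = x_tr_s[:, mask], x_te_s[:, mask]
        cv = StratifiedKFold(n_splits=protocol.cv_folds, shuffle=True, random_state=seed)
        for spec in specs:
            search = GridSearchCV(
                spec.build(seed), spec.grid, scoring="recall", cv=cv,
                refit=True, n_jobs=1, error_score="raise",
            )
            search.fit(x_tr_s, y_tr)
            pred = search.predict(x_te_s)
            scores = _positive_scores(search.best_estimator_, x_te_s)
            tp = int(((pred == 1) & (y_te == 1)).sum())
            fn = int(((pred == 0) & (y_te == 1)).sum())
            results.append(SeedResult(
                seed=seed, classifier=spec.name,
                recall=recall_score(y_te, pred, 1),
                auc=auc_score(y_te, scores, 1),
                tp=tp, fn=fn, params=dict(search.best_params_),
            ))

    names = [s.name for s in specs]
    mean_recall = {n: float(np.mean([r.recall for r in results if r.classifier == n]))
                   for n in names}
    mean_auc = {n: float(np.mean([r.auc for r in results if r.classifier == n]))
                for n in names}
    best = max(names, key=lambda n: (mean_recall[n], mean_auc[n]))
    return EvaluationReport(results, mean_recall, mean_auc, best)
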