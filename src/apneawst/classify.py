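"""Random-forest classification of apnea minutes with repeated CV protocols.

The positive class is *apnea*. Two validation schemes are provided —
stratified 50/50 hold-out and stratified 10-fold — each repeated (default
ten times) with mean +/- std reporting of accuracy, sensitivity,
specificity, precision, F1, Cohen's kappa and ROC AUC. All per-fold
normalization (z-score) and optional PCA are fitted on training rows only.
A comparison harness runs the ten reference classifiers on identical
splits.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .features import ZScoreStats

logger = logging.getLogger(__name__)

POSITIVE = 1  # apnea
METRIC_NAMES = ["acc", "sen", "spe", "precision", "f1", "kappa", "auc"]


@dataclass
class ConfusionMatrix:
    """Binary confusion counts with apnea as the positive class."""

    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be nonnegative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    @classmethod
    def from_predictions(cls, y_true, y_pred) -> "ConfusionMatrix":
        y_true = np.asarray(y_true)
        y_pred = np.asarray(y_pred)
        return cls(tp=int(((y_true == POSITIVE) & (y_pred == POSITIVE)).sum()),
                   tn=int(((y_true != POSITIVE) & (y_pred != POSITIVE)).sum()),
                   fp=int(((y_true != POSITIVE) & (y_pred == POSITIVE)).sum()),
                   fn=int(((y_true == POSITIVE) & (y_pred != POSITIVE)).sum()))


def confusion_metrics(cm: ConfusionMatrix) -> dict[str, float]:
    """Accuracy, sensitivity, specificity, precision and F1 from counts.

    Ratios with a zero denominator are returned as ``nan`` (flagged
    undefined) rather than silently substituted.
    """
    if cm.total == 0:
        raise ValueError("empty confusion matrix")

    def ratio(num: int, den: int) -> float:
        return num / den if den else float("nan")

    acc = (cm.tp + cm.tn) / cm.total
    sen = ratio(cm.tp, cm.tp + cm.fn)
    spe = ratio(cm.tn, cm.tn + cm.fp)
    precision = ratio(cm.tp, cm.tp + cm.fp)
    if np.isnan(precision) or np.isnan(sen) or precision + sen == 0:
        f1 = float("nan")
    else:
        f1 = 2 * precision * sen / (precision + sen)
    return {"acc": acc, "sen": sen, "spe": spe, "precision": precision,
            "f1": f1}


def cohen_kappa(cm: ConfusionMatrix) -> float:
    """Chance-corrected agreement (p_o - p_e) / (1 - p_e)."""
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    n = cm.total
    p_o = (cm.tp + cm.tn) / n
    p_pos = ((cm.tp + cm.fn) / n) * ((cm.tp + cm.fp) / n)
    p_neg = ((cm.tn + cm.fp) / n) * ((cm.tn + cm.fn) / n)
    p_e = p_pos + p_neg
    if p_e == 1.0:
        return float("nan")
    return (p_o - p_e) / (1.0 - p_e)


def roc_auc(scores, labels) -> float:
    """Area under the ROC via the rank (Mann-Whitney) statistic, ties averaged."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos = labels == POSITIVE
    n_pos, n_neg = int(pos.sum()), int((~pos).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present to compute AUC")
    ranks = rankdata(scores)
    return float((ranks[pos].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


# ---------------------------------------------------------------------------
# Classifier registry
# ---------------------------------------------------------------------------

RF_DEFAULTS = {"n_estimators": 500, "max_features": "sqrt", "max_depth": None}


def make_classifier(name: str, seed: int = 0, **hyperparams):
    """Instantiate one of the comparison classifiers by name."""
    from sklearn.discriminant_analysis import (LinearDiscriminantAnalysis,
                                               QuadraticDiscriminantAnalysis)
    from sklearn.ensemble import (AdaBoostClassifier, ExtraTreesClassifier,
                                  RandomForestClassifier)
    from sklearn.linear_model import LogisticRegression, SGDClassifier
    from sklearn.naive_bayes import GaussianNB
    from sklearn.neighbors import KNeighborsClassifier
    from sklearn.svm import SVC

    registry = {
        "AdaBoost": lambda: AdaBoostClassifier(random_state=seed),
        "ExtraTrees": lambda: ExtraTreesClassifier(
            n_estimators=hyperparams.pop("n_estimators", 500),
            random_state=seed),
        "GaussianNB": lambda: GaussianNB(),
        "KNN": lambda: KNeighborsClassifier(),
        "LDA": lambda: LinearDiscriminantAnalysis(),
        "LR": lambda: LogisticRegression(max_iter=2000, random_state=seed),
        "QDA": lambda: QuadraticDiscriminantAnalysis(),
        "RF": lambda: RandomForestClassifier(
            random_state=seed, **{**RF_DEFAULTS, **hyperparams}),
        "SGD": lambda: SGDClassifier(loss="log_loss", random_state=seed),
        "SVM": lambda: SVC(random_state=seed),
        "XgBoost": lambda: _xgboost(seed, **hyperparams),
    }
    if name not in registry:
        raise ValueError(f"unknown classifier {name!r}; "
                         f"choose from {sorted(registry)}")
    return registry[name]()


def _xgboost(seed: int, **hyperparams):
    from xgboost import XGBClassifier
    return XGBClassifier(random_state=seed, verbosity=0, n_jobs=1,
                         eval_metric="logloss", **hyperparams)


def train_random_forest(X, y, seed: int = 0, **hyperparams):
    """Fit the default random forest (500 trees, sqrt-p splits)."""
    model = make_classifier("RF", seed=seed, **hyperparams)
    model.fit(X, y)
    return model


def _scores(model, X) -> np.ndarray:
    """Continuous scores for AUC: positive-class probability when available,
    otherwise the decision function."""
    if hasattr(model, "predict_proba"):
        classes = list(model.classes_)
        return model.predict_proba(X)[:, classes.index(POSITIVE)]
    return model.decision_function(X)


# ---------------------------------------------------------------------------
# Cross-validation protocols
# ---------------------------------------------------------------------------

@dataclass
class CvConfig:
    """Validation protocol configuration.

    ``scheme`` is ``"holdout_50_50"`` (stratified half/half split) or
    ``"kfold_10"`` (stratified k-fold). ``repeats`` draws fresh splits each
    time. ``subject_wise=True`` makes the hold-out split group-aware so no
    recording contributes to both halves.
    """

    scheme: str = "kfold_10"
    repeats: int = 10
    seed: int = 0
    classifier: str = "RF"
    hyperparams: dict = field(default_factory=dict)
    n_folds: int = 10
    pca_variance: float | None = None
    subject_wise: bool = False

    def __post_init__(self) -> None:
        if self.scheme not in ("holdout_50_50", "kfold_10"):
            raise ValueError(f"unknown scheme {self.scheme!r}")
        if self.repeats < 1:
            raise ValueError("repeats must be >= 1")


@dataclass
class MetricsReport:
    """Mean +/- std of each metric over CV repeats, raw values retained."""

    classifier: str
    scheme: str
    per_repeat: pd.DataFrame  # one row per repeat, columns METRIC_NAMES

    def mean(self, metric: str) -> float:
        return float(self.per_repeat[metric].mean())

    def std(self, metric: str) -> float:
        return float(self.per_repeat[metric].std(ddof=0))

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame({"mean": self.per_repeat.mean(),
                             "std": self.per_repeat.std(ddof=0)})

    def to_dict(self) -> dict:
        return {
            "classifier": self.classifier,
            "scheme": self.scheme,
            "metrics": {m: {"mean": self.mean(m), "std": self.std(m),
                            "per_repeat": self.per_repeat[m].tolist()}
                        for m in self.per_repeat.columns},
        }


def _splits_for_repeat(y, groups, config: CvConfig, rng_seed: int):
    """Train/test index pairs for one repeat of the configured scheme."""
    from sklearn.model_selection import (GroupShuffleSplit, StratifiedKFold,
                                         train_test_split)
    idx = np.arange(len(y))
    if config.scheme == "holdout_50_50":
        if config.subject_wise:
            if groups is None:
                raise ValueError("subject_wise hold-out needs groups")
            gss = GroupShuffleSplit(n_splits=1, test_size=0.5,
                                    random_state=rng_seed)
            return [next(gss.split(idx, y, groups))]
        tr, te = train_test_split(idx, test_size=0.5, stratify=y,
                                  random_state=rng_seed)
        return [(tr, te)]
    skf = StratifiedKFold(n_splits=config.n_folds, shuffle=True,
                          random_state=rng_seed)
    return list(skf.split(idx, y))


def _fit_eval_splits(X, y, splits, config: CvConfig, rng_seed: int):
    """Pool test predictions over the splits of one repeat -> metric dict."""
    y = np.asarray(y)
    all_true, all_pred, all_scores = [], [], []
    for tr, te in splits:
        stats = ZScoreStats().fit(X[tr])
        Xtr, Xte = stats.transform(X[tr]), stats.transform(X[te])
        if config.pca_variance is not None:
            Xtr, Xte = pca_reduce(Xtr, Xte, config.pca_variance,
                                  seed=rng_seed)
        model = make_classifier(config.classifier, seed=rng_seed,
                                **dict(config.hyperparams))
        model.fit(Xtr, y[tr])
        all_true.append(y[te])
        all_pred.append(model.predict(Xte))
        all_scores.append(_scores(model, Xte))
    y_true = np.concatenate(all_true)
    y_pred = np.concatenate(all_pred)
    cm = ConfusionMatrix.from_predictions(y_true, y_pred)
    metrics = confusion_metrics(cm)
    metrics["kappa"] = cohen_kappa(cm)
    metrics["auc"] = roc_auc(np.concatenate(all_scores), y_true)
    return metrics


def run_cv(X, y, config: CvConfig, groups=None) -> MetricsReport:
    """Run the configured validation protocol and aggregate over repeats.

    Normalization (and PCA, when requested) is fitted inside each training
    split only. A split that leaves a single class in some fold is redrawn
    with a logged warning.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if len(X) < 20:
        raise ValueError("need at least 20 rows for cross-validation")
    rows = []
    for rep in range(config.repeats):
        rng_seed = config.seed + rep
        for attempt in range(10):
            splits = _splits_for_repeat(y, groups, config, rng_seed + 1000 * attempt)
            if all(len(np.unique(y[tr])) == 2 and len(te) > 0
                   for tr, te in splits):
                if attempt:
                    logger.warning("repeat %d: redrew split %d time(s) to get "
                                   "both classes in training folds", rep, attempt)
                break
        else:
            raise RuntimeError("could not draw a split with both classes")
        rows.append(_fit_eval_splits(X, y, splits, config, rng_seed))
    return MetricsReport(classifier=config.classifier, scheme=config.scheme,
                         per_repeat=pd.DataFrame(rows, columns=METRIC_NAMES))


def compare_classifiers(X, y, config: CvConfig,
                        names: list[str] | None = None,
                        groups=None) -> dict[str, MetricsReport]:
    """Run every named classifier on identical repeated splits."""
    names = names or ["AdaBoost", "ExtraTrees", "GaussianNB", "KNN", "LDA",
                      "LR", "QDA", "RF", "SGD", "SVM", "XgBoost"]
    reports = {}
    for name in names:
        cfg = CvConfig(scheme=config.scheme, repeats=config.repeats,
                       seed=config.seed, classifier=name,
                       hyperparams=dict(config.hyperparams) if name in
                       ("RF", "ExtraTrees", "XgBoost") else {},
                       n_folds=config.n_folds,
                       pca_variance=config.pca_variance,
                       subject_wise=config.subject_wise)
        reports[name] = run_cv(X, y, cfg, groups=groups)
    return reports


# ---------------------------------------------------------------------------
# Dimensionality reduction and feature selection
# ---------------------------------------------------------------------------

def pca_reduce(train: np.ndarray, test: np.ndarray, variance_target: float,
               seed: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """Project train/test onto the principal components of the training rows
    that retain at least ``variance_target`` of the training variance."""
    from sklearn.decomposition import PCA
    if not 0 < variance_target <= 1:
        raise ValueError("variance_target must be in (0, 1]")
    n_components = None if variance_target == 1.0 else variance_target
    pca = PCA(n_components=n_components, svd_solver="full", random_state=seed)
    return pca.fit_transform(train), pca.transform(test)


def sequential_feature_selection(X, y, feature_names: list[str],
                                 k_target: int = 5,
                                 direction: str = "forward",
                                 seed: int = 0, cv: int = 5,
                                 n_estimators: int = 100):
    """Greedy CV-scored feature selection down/up to ``k_target`` features.

    The scorer is mean accuracy of a seeded random forest under an internal
    stratified ``cv``-fold split of the (z-scored) data. ``direction``
    ``"forward"`` adds the best feature each round; ``"bidirectional"``
    additionally tries dropping previously added features whenever that
    improves the score (floating selection). Returns ``(selected_names,
    history)`` where history records each accepted step's feature set and
    score — the addition order is the importance ranking.
    """
    from sklearn.ensemble import RandomForestClassifier
    from sklearn.model_selection import StratifiedKFold, cross_val_score

    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    p = X.shape[1]
    if len(feature_names) != p:
        raise ValueError("feature_names length must match X columns")
    if k_target > p:
        raise ValueError(f"k_target={k_target} exceeds {p} features")
    if direction not in ("forward", "bidirectional"):
        raise ValueError(f"unknown direction {direction!r}")

    skf = StratifiedKFold(n_splits=cv, shuffle=True, random_state=seed)

    def score(cols: list[int]) -> float:
        model = RandomForestClassifier(n_estimators=n_estimators,
                                       random_state=seed)
        return float(cross_val_score(model, X[:, cols], y, cv=skf,
                                     scoring="accuracy").mean())

    selected: list[int] = []
    history = []
    while len(selected) < k_target:
        best_j, best_s = None, -np.inf
        for j in range(p):
            if j in selected:
                continue
            s = score(selected + [j])
            if s > best_s:
                best_j, best_s = j, s
        selected.append(best_j)
        history.append({"action": "add", "feature": feature_names[best_j],
                        "selected": [feature_names[i] for i in selected],
                        "score": best_s})
        if direction == "bidirectional" and len(selected) > 2:
            improved = True
            while improved and len(selected) > 2:
                improved = False
                current = history[-1]["score"]
                for j in list(selected[:-1]):
                    s = score([i for i in selected if i != j])
                    if s > current:
                        selected.remove(j)
                        history.append({
                            "action": "drop", "feature": feature_names[j],
                            "selected": [feature_names[i] for i in selected],
                            "score": s})
                        improved = True
                        break
    return [feature_names[i] for i in selected], history
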