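"""Global/non-global SO classification on flattened CD features.

The classifier is a bagged ensemble of 100 decision trees: each tree is
fit on a with-replacement bootstrap of the training rows, and the
ensemble posterior for a sample is the average of the per-tree class
probability estimates (the predicted class is the argmax). Performance
is summarised with the Matthews correlation coefficient (MCC), which
stays informative under the ~1:2 global:non-global class imbalance, and
evaluated with stratified 5-fold cross-validation pooled into a single
out-of-fold confusion matrix.

Per-feature importance for the optimisation objective comes from the
one-way ANOVA F statistic between the two label groups (univariate
feature ranking).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.ensemble import BaggingClassifier
from sklearn.feature_selection import f_classif
from sklearn.model_selection import ParameterSampler, StratifiedKFold
from sklearn.tree import DecisionTreeClassifier

GLOBAL_LABEL = 1  # positive class: "global"


@dataclass(frozen=True)
class ConfusionMatrix:
    """Binary counts with "global" as the positive class."""

    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


def confusion_from_predictions(y_true: np.ndarray, y_pred: np.ndarray) -> ConfusionMatrix:
    y_true = np.asarray(y_true).astype(int)
    y_pred = np.asarray(y_pred).astype(int)
    return ConfusionMatrix(
        tp=int(((y_true == 1) & (y_pred == 1)).sum()),
        tn=int(((y_true == 0) & (y_pred == 0)).sum()),
        fp=int(((y_true == 0) & (y_pred == 1)).sum()),
        fn=int(((y_true == 1) & (y_pred == 0)).sum()),
    )


def mcc(cm: ConfusionMatrix) -> float:
    """Matthews correlation coefficient in [−1, 1].

    (TP·TN − FP·FN) / √((TP+FP)(TP+FN)(TN+FP)(TN+FN)); returns 0 with a
    warning when any denominator factor is zero (standard convention).
    """
    tp, tn, fp, fn = cm.tp, cm.tn, cm.fp, cm.fn
    factors = [(tp + fp), (tp + fn), (tn + fp), (tn + fn)]
    if 0 in factors:
        warnings.warn("MCC denominator factor is zero; returning 0", stacklevel=2)
        return 0.0
    num = tp * tn - fp * fn
    denom = np.sqrt(np.prod(np.array(factors, dtype=float)))
    return float(num / denom)


@dataclass
class FeatureWeights:
    """Non-negative per-feature importances, one per flattened CD element."""

    w: np.ndarray

    def __post_init__(self) -> None:
        self.w = np.asarray(self.w, dtype=float)
        if self.w.ndim != 1:
            raise ValueError("weights must be a vector")
        if not np.all(np.isfinite(self.w)) or np.any(self.w < 0):
            raise ValueError("weights must be finite and non-negative")


def anova_f_weights(X: np.ndarray, y: np.ndarray) -> FeatureWeights:
    """One-way ANOVA F statistic per feature between the two label groups.

    Constant features (zero between- and within-group variance) get
    weight 0 rather than NaN.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y).astype(int)
    if X.shape[0] < 3:
        raise ValueError("need at least 3 samples for ANOVA weights")
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present to compute F weights")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        f, _ = f_classif(X, y)
    f = np.nan_to_num(f, nan=0.0, posinf=0.0)
    return FeatureWeights(w=np.maximum(f, 0.0))


@dataclass
class SOClassifier:
    """Bagged-trees global/non-global classifier over flattened CD features."""

    model: BaggingClassifier
    n_features: int
    seed: int
    hyperparams: dict = field(default_factory=dict)

    @property
    def trees(self):
        return self.model.estimators_


def _build_bagging(seed: int, n_trees: int, min_leaf: int, max_features) -> BaggingClassifier:
    base = DecisionTreeClassifier(min_samples_leaf=min_leaf,
                                  max_features=max_features,
                                  random_state=seed)
    return BaggingClassifier(estimator=base, n_estimators=n_trees,
                             bootstrap=True, random_state=seed)


def tune_hyperparameters(X: np.ndarray, y: np.ndarray, seed: int = 0,
                         n_trees: int = 100, n_iter: int = 8,
                         inner_folds: int = 5) -> dict:
    """Seeded randomized search over tree hyperparameters by inner-CV MCC.

    Samples {min leaf size, fraction of features considered per split}
    and scores each draw with stratified ``inner_folds``-fold pooled MCC.
    """
    space = {"min_leaf": [1, 2, 4, 8, 16], "max_features": [0.2, 0.5, 0.8, 1.0]}
    sampler = ParameterSampler(space, n_iter=n_iter,
                               random_state=np.random.RandomState(seed))
    best, best_score = {"min_leaf": 1, "max_features": 1.0}, -np.inf
    for cand in sampler:
        score = crossval_mcc(X, y, folds=inner_folds, seed=seed,
                             n_trees=max(n_trees // 4, 10), tune=False,
                             min_leaf=cand["min_leaf"],
                             max_features=cand["max_features"])
        if score > best_score:
            best, best_score = dict(cand), score
    return best


def train(X: np.ndarray, y: np.ndarray, seed: int = 0, n_trees: int = 100,
          tune: bool = False, min_leaf: int = 1,
          max_features: float = 1.0) -> SOClassifier:
    """Fit the bagged-trees ensemble; deterministic for a fixed seed.

    ``y`` is binary with 1 = global. With ``tune=True`` the tree
    hyperparameters are first chosen by a seeded randomized search with
    inner cross-validation.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y).astype(int)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("need a 2-D feature matrix with at least 2 rows")
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present for training")
    hp = {"min_leaf": min_leaf, "max_features": max_features}
    if tune:
        hp = tune_hyperparameters(X, y, seed=seed, n_trees=n_trees)
    model = _build_bagging(seed, n_trees, hp["min_leaf"], hp["max_features"])
    model.fit(X, y)
    return SOClassifier(model=model, n_features=X.shape[1], seed=seed,
                        hyperparams=hp)


def posterior(clf: SOClassifier, x: np.ndarray) -> float | np.ndarray:
    """Posterior probability of the "global" class (mean over trees)."""
    x = np.asarray(x, dtype=float)
    single = x.ndim == 1
    X = np.atleast_2d(x)
    if X.shape[1] != clf.n_features:
        raise ValueError(
            f"feature length {X.shape[1]} does not match model ({clf.n_features})"
        )
    classes = list(clf.model.classes_)
    p = clf.model.predict_proba(X)[:, classes.index(GLOBAL_LABEL)]
    return float(p[0]) if single else p


def predict(clf: SOClassifier, x: np.ndarray) -> np.ndarray:
    p = np.atleast_1d(posterior(clf, x))
    return (p >= 0.5).astype(int)


def crossval_mcc(X: np.ndarray, y: np.ndarray, folds: int = 5, seed: int = 0,
                 n_trees: int = 100, tune: bool = False, min_leaf: int = 1,
                 max_features: float = 1.0) -> float:
    """Stratified k-fold CV; MCC of the pooled out-of-fold confusion matrix."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y).astype(int)
    if X.shape[0] < folds:
        raise ValueError("fewer samples than folds")
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    y_pred = np.empty_like(y)
    for i, (tr, te) in enumerate(skf.split(X, y)):
        if len(np.unique(y[tr])) < 2:
            raise ValueError("a training fold lost one class; reduce folds")
        clf = train(X[tr], y[tr], seed=seed + i, n_trees=n_trees, tune=tune,
                    min_leaf=min_leaf, max_features=max_features)
        y_pred[te] = predict(clf, X[te])
    return mcc(confusion_from_predictions(y, y_pred))
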