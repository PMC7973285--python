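"""Classifier comparison, soft-voting ensemble, and evaluation protocols.

The applicator-selection model is built in four stages: (1) random
oversampling of the minority applicator class inside every training split;
(2) nested 5-fold cross-validation (inner grid search, outer performance
estimation) of twelve candidate classification algorithms, with plan-quality
sample weights where the algorithm supports them; (3) a soft-voting ensemble
of the top three weighted models (by default the tree ensembles AdaBoost,
gradient boosting, and random forest); (4) repeated stratified 85/15
hold-out evaluation and leave-one-out cross-validation, plus impurity-based
feature-importance reporting.

IS (hybrid interstitial) is the positive class throughout: recall measures
how reliably fractions that need interstitial needles are flagged. Soft-vote
ties go to IS for the same reason.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin, clone
from sklearn.discriminant_analysis import (
    LinearDiscriminantAnalysis,
    QuadraticDiscriminantAnalysis,
)
from sklearn.ensemble import (
    AdaBoostClassifier,
    GradientBoostingClassifier,
    RandomForestClassifier,
)
from sklearn.gaussian_process import GaussianProcessClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import (
    accuracy_score,
    f1_score,
    precision_score,
    recall_score,
    roc_auc_score,
)
from sklearn.model_selection import GridSearchCV, KFold, train_test_split
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier, NearestCentroid
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import NuSVC
from sklearn.utils.validation import check_is_fitted

__all__ = [
    "POSITIVE_CLASS",
    "CLASSES",
    "AlgorithmSpec",
    "ALGORITHM_REGISTRY",
    "WeightedSample",
    "make_estimator",
    "oversample_minority",
    "nested_cv",
    "NestedCVResult",
    "compare_algorithms",
    "soft_vote",
    "ApplicatorVotingClassifier",
    "evaluate_voting",
    "loocv",
    "feature_importances",
]

POSITIVE_CLASS = "IS"
CLASSES = ("IC", "IS")
METRIC_NAMES = ("accuracy", "precision", "recall", "f1", "roc_auc")


@dataclass(frozen=True)
class AlgorithmSpec:
    """One candidate classification algorithm.

    ``supports_weights`` records whether the algorithm's ``fit`` accepts
    per-sample weights; only those algorithms get a weighted variant in the
    comparison. ``grid`` is the hyperparameter search space of the inner
    cross-validation (deliberately small, overridable).
    """

    abbreviation: str
    name: str
    supports_weights: bool
    grid: Mapping[str, Sequence] = field(default_factory=dict)
    scale: bool = False  # wrap in a standardizing pipeline


#: The twelve compared algorithms. Weight support: ABC, GNB, GBC, LRC,
#: NuSVC, RFC.
ALGORITHM_REGISTRY: dict[str, AlgorithmSpec] = {
    s.abbreviation: s
    for s in [
        AlgorithmSpec("ABC", "AdaBoost Classifier", True,
                      {"n_estimators": [50, 100], "learning_rate": [0.5, 1.0]}),
        AlgorithmSpec("GNB", "Gaussian Naive Bayes Classifier", True,
                      {"var_smoothing": [1e-9, 1e-6]}),
        AlgorithmSpec("GPC", "Gaussian Process Classifier", False, {}, scale=True),
        AlgorithmSpec("GBC", "Gradient Boosting Classifier", True,
                      {"n_estimators": [50, 100], "max_depth": [2, 3]}),
        AlgorithmSpec("KNN", "K-Nearest Neighbours Classifier", False,
                      {"n_neighbors": [3, 5, 7]}, scale=True),
        AlgorithmSpec("LDA", "Linear Discriminant Analysis", False, {}),
        AlgorithmSpec("LRC", "Logistic Regression Classifier", True,
                      {"C": [0.1, 1.0, 10.0]}, scale=True),
        AlgorithmSpec("MLPC", "Multi-layer Perceptron Classifier", False,
                      {"hidden_layer_sizes": [(8,), (16,)]}, scale=True),
        AlgorithmSpec("NCC", "Nearest Centroid Classifier", False, {}, scale=True),
        AlgorithmSpec("NuSVC", "Nu-Support Vector Classifier", True,
                      {"nu": [0.3, 0.5]}, scale=True),
        AlgorithmSpec("QDA", "Quadratic Discriminant Analysis", False,
                      {"reg_param": [0.0, 0.1]}),
        AlgorithmSpec("RFC", "Random Forest Classifier", True,
                      {"n_estimators": [100], "max_depth": [3, 5, None]}),
    ]
}


@dataclass
class WeightedSample:
    """One training fraction: reduced features, label, plan-quality weight."""

    features: np.ndarray
    label: str
    weight: float = 1.0
    fraction_id: str | int | None = None

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=float)
        if self.label not in CLASSES:
            raise ValueError(f"label must be one of {CLASSES}, got {self.label!r}")
        if not np.isfinite(self.features).all():
            raise ValueError("features must be finite after reduction")


def samples_to_arrays(
    samples: Sequence[WeightedSample],
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    X = np.vstack([s.features for s in samples])
    y = np.array([s.label for s in samples])
    w = np.array([s.weight for s in samples], dtype=float)
    return X, y, w


def _base_estimator(abbrev: str, random_state: int | None) -> BaseEstimator:
    if abbrev == "ABC":
        return AdaBoostClassifier(random_state=random_state)
    if abbrev == "GNB":
        return GaussianNB()
    if abbrev == "GPC":
        return GaussianProcessClassifier(random_state=random_state)
    if abbrev == "GBC":
        return GradientBoostingClassifier(random_state=random_state)
    if abbrev == "KNN":
        return KNeighborsClassifier()
    if abbrev == "LDA":
        return LinearDiscriminantAnalysis()
    if abbrev == "LRC":
        return LogisticRegression(max_iter=1000, random_state=random_state)
    if abbrev == "MLPC":
        return MLPClassifier(max_iter=600, random_state=random_state)
    if abbrev == "NCC":
        return NearestCentroid()
    if abbrev == "NuSVC":
        return NuSVC(random_state=random_state)
    if abbrev == "QDA":
        return QuadraticDiscriminantAnalysis()
    if abbrev == "RFC":
        return RandomForestClassifier(random_state=random_state)
    raise KeyError(f"unknown algorithm abbreviation {abbrev!r}")


def make_estimator(
    abbrev: str,
    random_state: int | None = None,
    params: Mapping | None = None,
) -> BaseEstimator:
    """Build the estimator for a registry entry; scale-sensitive algorithms
    are wrapped in a standardizing pipeline whose final step is named
    ``clf``."""
    spec = ALGORITHM_REGISTRY[abbrev]
    est = _base_estimator(abbrev, random_state)
    if spec.scale:
        est = Pipeline([("scale", StandardScaler()), ("clf", est)])
    if params:
        try:
            est.set_params(**dict(params))
        except ValueError as exc:
            raise ValueError(f"invalid hyperparameter for {abbrev}: {exc}") from exc
    return est


def _prefix_grid(spec: AlgorithmSpec, grid: Mapping | None) -> dict:
    g = dict(grid) if grid is not None else dict(spec.grid)
    if spec.scale:
        g = {k if "__" in k else f"clf__{k}": v for k, v in g.items()}
    return g


def _weight_param(est: BaseEstimator) -> str:
    return "clf__sample_weight" if isinstance(est, Pipeline) else "sample_weight"


def oversample_minority(
    X: np.ndarray,
    y: np.ndarray,
    sample_weight: np.ndarray | None = None,
    seed: int | None = 0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Random oversampling of the minority class to exact balance.

    Minority samples are duplicated by seeded sampling with replacement
    until class counts are equal; weights travel with their samples. Must be
    applied inside training splits only — test data stays untouched.

    Returns ``(X_os, y_os, w_os, source_index)`` where ``source_index[i]``
    is the row of the input that output row ``i`` copies (the first ``len(X)``
    entries are ``0..len(X)-1``).
    """
    y = np.asarray(y)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("oversampling requires two classes in the input")
    X = np.asarray(X, dtype=float)
    w = np.ones(len(y)) if sample_weight is None else np.asarray(sample_weight, float)
    minority = classes[np.argmin(counts)]
    deficit = int(counts.max() - counts.min())
    idx_min = np.flatnonzero(y == minority)
    rng = np.random.default_rng(seed)
    extra = rng.choice(idx_min, size=deficit, replace=True)
    source = np.concatenate([np.arange(len(y)), extra])
    return X[source], y[source], w[source], source


def _scores_for_auc(est: BaseEstimator, X: np.ndarray, y_pred: np.ndarray) -> np.ndarray:
    """A continuous score for the positive (IS) class, falling back from
    probabilities to decision values to hard predictions."""
    if hasattr(est, "predict_proba"):
        proba = est.predict_proba(X)
        j = list(est.classes_).index(POSITIVE_CLASS)
        return proba[:, j]
    if hasattr(est, "decision_function"):
        d = est.decision_function(X)
        return d if est.classes_[1] == POSITIVE_CLASS else -d
    return (y_pred == POSITIVE_CLASS).astype(float)


def _compute_metrics(y_true, y_pred, scores) -> dict[str, float]:
    out = {
        "accuracy": accuracy_score(y_true, y_pred),
        "precision": precision_score(
            y_true, y_pred, pos_label=POSITIVE_CLASS, zero_division=0
        ),
        "recall": recall_score(
            y_true, y_pred, pos_label=POSITIVE_CLASS, zero_division=0
        ),
        "f1": f1_score(y_true, y_pred, pos_label=POSITIVE_CLASS, zero_division=0),
    }
    if len(np.unique(y_true)) == 2:
        out["roc_auc"] = roc_auc_score(np.asarray(y_true) == POSITIVE_CLASS, scores)
    else:  # degenerate single-class test fold
        out["roc_auc"] = np.nan
    return {k: float(v) for k, v in out.items()}


@dataclass
class NestedCVResult:
    """Outcome of one nested-CV iteration for one algorithm variant."""

    abbreviation: str
    use_weights: bool
    iteration: int
    metrics: dict[str, float]
    fold_metrics: pd.DataFrame
    chosen_params: list[dict]
    outer_test_indices: list[np.ndarray]


def nested_cv(
    algorithm: AlgorithmSpec | str,
    X: np.ndarray,
    y: np.ndarray,
    sample_weight: np.ndarray | None = None,
    use_weights: bool = False,
    iteration: int = 0,
    outer_splits: int = 5,
    inner_splits: int = 5,
    oversample: bool = True,
    grid: Mapping | None = None,
) -> NestedCVResult:
    """One iteration of nested K-fold cross-validation for one algorithm.

    Outer folds (shuffled, random_state = iteration number) estimate
    performance; within each outer training set, a grid search over the
    algorithm's hyperparameter grid maximizes inner K-fold accuracy. The
    minority class is oversampled inside the outer training set only, so
    outer test folds contain only original samples. Sample weights are used
    for fitting iff ``use_weights`` and the algorithm supports them; inner
    scoring is unweighted accuracy.
    """
    spec = ALGORITHM_REGISTRY[algorithm] if isinstance(algorithm, str) else algorithm
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    w = np.ones(len(y)) if sample_weight is None else np.asarray(sample_weight, float)
    param_grid = _prefix_grid(spec, grid)

    outer = KFold(n_splits=outer_splits, shuffle=True, random_state=iteration)
    fold_rows, chosen, test_indices = [], [], []
    for fold, (tr, te) in enumerate(outer.split(X)):
        Xtr, ytr, wtr = X[tr], y[tr], w[tr]
        if oversample:
            Xtr, ytr, wtr, _ = oversample_minority(
                Xtr, ytr, wtr, seed=iteration * outer_splits + fold
            )
        est = make_estimator(spec.abbreviation, random_state=iteration)
        inner = KFold(n_splits=inner_splits, shuffle=True, random_state=iteration)
        gs = GridSearchCV(est, param_grid, cv=inner, scoring="accuracy", refit=True)
        fit_kwargs = {}
        if use_weights and spec.supports_weights:
            fit_kwargs[_weight_param(est)] = wtr
        gs.fit(Xtr, ytr, **fit_kwargs)
        best = gs.best_estimator_
        y_pred = best.predict(X[te])
        fold_rows.append(
            _compute_metrics(y[te], y_pred, _scores_for_auc(best, X[te], y_pred))
        )
        chosen.append(dict(gs.best_params_))
        test_indices.append(te)

    fold_df = pd.DataFrame(fold_rows)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean_metrics = {m: float(np.nanmean(fold_df[m])) for m in METRIC_NAMES}
    return NestedCVResult(
        abbreviation=spec.abbreviation,
        use_weights=use_weights,
        iteration=iteration,
        metrics=mean_metrics,
        fold_metrics=fold_df,
        chosen_params=chosen,
        outer_test_indices=test_indices,
    )


def compare_algorithms(
    X: np.ndarray,
    y: np.ndarray,
    sample_weight: np.ndarray | None = None,
    registry: Mapping[str, AlgorithmSpec] | None = None,
    n_iterations: int = 100,
    n_top: int = 3,
    iteration_offset: int = 0,
    **cv_kwargs,
) -> tuple[list[str], pd.DataFrame]:
    """Rank algorithm variants by mean nested-CV accuracy over iterations.

    Weight-capable algorithms are evaluated both with and without
    plan-quality sample weights (two ranked variants); others contribute one
    unweighted variant. Returns ``(top_members, report)`` where
    ``top_members`` are the ``n_top`` best weighted variants' abbreviations
    (the voting-ensemble members) and ``report`` holds one row per variant
    and iteration. ``iteration_offset`` shifts the iteration seeds so two
    runs can use disjoint seed ranges (e.g. for ranking-stability checks).
    """
    registry = dict(registry if registry is not None else ALGORITHM_REGISTRY)
    if not registry:
        raise ValueError("empty algorithm registry")
    rows = []
    for abbrev, spec in registry.items():
        variants = [True, False] if spec.supports_weights else [False]
        for use_w in variants:
            for it in range(iteration_offset, iteration_offset + n_iterations):
                res = nested_cv(
                    spec, X, y, sample_weight,
                    use_weights=use_w, iteration=it, **cv_kwargs,
                )
                rows.append(
                    {"algorithm": abbrev, "weighted": use_w, "iteration": it,
                     **res.metrics}
                )
    report = pd.DataFrame(rows)
    ranking = (
        report.groupby(["algorithm", "weighted"])["accuracy"]
        .mean()
        .sort_values(ascending=False)
    )
    weighted_ranked = [alg for (alg, w) in ranking.index if w]
    if not weighted_ranked:  # registry without any weight-capable algorithm
        weighted_ranked = [alg for (alg, _) in ranking.index]
    top = list(dict.fromkeys(weighted_ranked))[:n_top]
    return top, report


def soft_vote(
    member_probabilities: Sequence[Sequence[float]],
) -> tuple[str, float]:
    """Combine member class probabilities by equal-weight averaging.

    Each member contributes ``(p_IC, p_IS)`` summing to 1. The class is the
    argmax of the averaged probabilities; an exact tie goes to IS (the class
    whose misses carry the clinical cost of an underdosed target).
    """
    probs = np.asarray(member_probabilities, dtype=float)
    if probs.ndim != 2 or probs.shape[1] != 2:
        raise ValueError("expected pairs (p_IC, p_IS)")
    if not np.allclose(probs.sum(axis=1), 1.0, atol=1e-6):
        raise ValueError("each probability pair must sum to 1")
    p_ic, p_is = probs.mean(axis=0)
    return (POSITIVE_CLASS if p_is >= p_ic else "IC", float(p_is))


class ApplicatorVotingClassifier(ClassifierMixin, BaseEstimator):
    """Soft-voting ensemble of the top individual models.

    On ``fit``, the minority class of the training set is oversampled to
    balance, then each member algorithm is tuned by an inner K-fold grid
    search (accuracy) and refit with plan-quality sample weights where
    supported. Prediction averages the members' class probabilities with
    equal weights; ties go to IS.

    Parameters
    ----------
    members : tuple of str
        Registry abbreviations of the member algorithms (default the three
        tree ensembles ABC, GBC, RFC).
    tune : bool
        If False, skip the inner grid search and fit each member at its
        default hyperparameters (used by leave-one-out evaluation, where n
        refits make the search prohibitive).
    inner_splits : int
        Folds of the inner tuning cross-validation.
    oversample : bool
        Oversample the minority class inside ``fit``.
    grids : mapping, optional
        Per-member hyperparameter grids overriding the registry defaults.
    random_state : int or None
        Seeds the oversampler, the inner folds, and member internals.

    Attributes
    ----------
    classes_ : ndarray, ("IC", "IS")
    members_ : list of fitted estimators
    member_params_ : list of dict, chosen hyperparameters per member
    """

    def __init__(
        self,
        members: tuple[str, ...] = ("ABC", "GBC", "RFC"),
        tune: bool = True,
        inner_splits: int = 5,
        oversample: bool = True,
        grids: Mapping[str, Mapping] | None = None,
        random_state: int | None = None,
    ):
        self.members = members
        self.tune = tune
        self.inner_splits = inner_splits
        self.oversample = oversample
        self.grids = grids
        self.random_state = random_state

    def fit(self, X, y, sample_weight=None) -> "ApplicatorVotingClassifier":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if X.ndim != 2 or not np.isfinite(X).all():
            raise ValueError("X must be a finite 2D array")
        if set(np.unique(y)) - set(CLASSES):
            raise ValueError(f"labels must be in {CLASSES}")
        w = (
            np.ones(len(y))
            if sample_weight is None
            else np.asarray(sample_weight, dtype=float)
        )
        if self.oversample:
            X, y, w, _ = oversample_minority(X, y, w, seed=self.random_state)
        elif len(np.unique(y)) < 2:
            raise ValueError("training data contains a single class")

        self.classes_ = np.array(CLASSES)
        self.members_, self.member_params_ = [], []
        for abbrev in self.members:
            spec = ALGORITHM_REGISTRY[abbrev]
            est = make_estimator(abbrev, random_state=self.random_state)
            fit_kwargs = (
                {_weight_param(est): w} if spec.supports_weights else {}
            )
            if self.tune:
                grid = _prefix_grid(
                    spec, (self.grids or {}).get(abbrev)
                )
                inner = KFold(
                    n_splits=self.inner_splits,
                    shuffle=True,
                    random_state=self.random_state,
                )
                gs = GridSearchCV(est, grid, cv=inner, scoring="accuracy")
                gs.fit(X, y, **fit_kwargs)
                self.members_.append(gs.best_estimator_)
                self.member_params_.append(dict(gs.best_params_))
            else:
                est.fit(X, y, **fit_kwargs)
                self.members_.append(est)
                self.member_params_.append({})
        self.n_features_in_ = X.shape[1]
        return self

    def _member_proba(self, est, X) -> np.ndarray:
        proba = est.predict_proba(X)
        cols = [list(est.classes_).index(c) for c in self.classes_]
        return proba[:, cols]

    def predict_proba(self, X) -> np.ndarray:
        check_is_fitted(self, "members_")
        X = np.asarray(X, dtype=float)
        stacked = np.stack([self._member_proba(m, X) for m in self.members_])
        return stacked.mean(axis=0)

    def predict(self, X) -> np.ndarray:
        proba = self.predict_proba(X)
        # tie (p_IS == p_IC) resolves to IS
        return np.where(proba[:, 1] >= proba[:, 0], POSITIVE_CLASS, "IC")


def evaluate_voting(
    X: np.ndarray,
    y: np.ndarray,
    sample_weight: np.ndarray | None = None,
    n_iterations: int = 1000,
    test_size: float = 0.15,
    model_builder: Callable[[int], ApplicatorVotingClassifier] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Repeated stratified hold-out evaluation of the voting model.

    Per iteration ``i``: a stratified train (1 - test_size) / test split
    with ``random_state=i``; members are tuned and fit on the training part
    (with oversampling and weights, seeds derived from ``i``); all five
    metrics are computed on the untouched test part. Returns
    ``(per_iteration, summary)`` where summary holds mean and SD per metric.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    w = np.ones(len(y)) if sample_weight is None else np.asarray(sample_weight, float)
    if model_builder is None:
        model_builder = lambda i: ApplicatorVotingClassifier(random_state=i)
    rows = []
    for i in range(n_iterations):
        Xtr, Xte, ytr, yte, wtr, _ = train_test_split(
            X, y, w, test_size=test_size, stratify=y, random_state=i
        )
        clf = model_builder(i).fit(Xtr, ytr, sample_weight=wtr)
        y_pred = clf.predict(Xte)
        scores = clf.predict_proba(Xte)[:, 1]
        rows.append({"iteration": i, **_compute_metrics(yte, y_pred, scores)})
    per_iter = pd.DataFrame(rows).set_index("iteration")
    summary = per_iter.agg(["mean", "std"]).T
    return per_iter, summary


def loocv(
    X: np.ndarray,
    y: np.ndarray,
    sample_weight: np.ndarray | None = None,
    model_builder: Callable[[], ApplicatorVotingClassifier] | None = None,
) -> float:
    """Leave-one-out accuracy of the voting model.

    Every sample is the test set exactly once, so no split seeding exists;
    member internal random states are fixed at 0. By default members are fit
    at their registry-default hyperparameters (``tune=False``) to keep the n
    refits tractable; pass a custom ``model_builder`` to tune.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if len(y) < 3:
        raise ValueError("LOOCV needs at least 3 samples")
    w = np.ones(len(y)) if sample_weight is None else np.asarray(sample_weight, float)
    if model_builder is None:
        model_builder = lambda: ApplicatorVotingClassifier(tune=False, random_state=0)
    correct = 0
    for i in range(len(y)):
        tr = np.delete(np.arange(len(y)), i)
        clf = model_builder().fit(X[tr], y[tr], sample_weight=w[tr])
        correct += int(clf.predict(X[i : i + 1])[0] == y[i])
    return correct / len(y)


def feature_importances(
    model: ApplicatorVotingClassifier,
    feature_names: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Impurity-based relative feature importances of the voting members.

    Returns a DataFrame (feature x member) of importances normalized to sum
    to 1 per member. Members without tree-style importances (no
    ``feature_importances_``) are omitted with a warning.
    """
    check_is_fitted(model, "members_")
    cols = {}
    for abbrev, est in zip(model.members, model.members_):
        base = est.named_steps["clf"] if isinstance(est, Pipeline) else est
        imp = getattr(base, "feature_importances_", None)
        if imp is None:
            warnings.warn(
                f"member {abbrev} has no impurity-based importances; omitted",
                UserWarning,
            )
            continue
        total = imp.sum()
        cols[abbrev] = imp / total if total > 0 else imp
    if feature_names is None:
        feature_names = [f"feature_{i}" for i in range(model.n_features_in_)]
    return pd.DataFrame(cols, index=pd.Index(feature_names, name="feature"))
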