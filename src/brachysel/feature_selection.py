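"""Univariate feature scoring and the reduction to HR-CTV geometry metrics.

Two filter scores are computed per feature against the applicator class:
the one-way ANOVA F statistic (between-class over within-class mean square)
and the mutual information between feature and class, estimated with the
k-nearest-neighbour estimator for continuous features against a discrete
target. The headline reduction keeps the six HR-CTV geometry metrics —
the group that dominates both rankings — while a data-driven top-k
intersection rule is available as the generalization.
"""

from __future__ import annotations

import warnings
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.feature_selection import SelectorMixin, f_classif, mutual_info_classif
from sklearn.utils.validation import check_is_fitted

from .geometry import DISPLAY_NAMES, FEATURE_NAMES, HRCTV_FEATURES

__all__ = [
    "anova_f",
    "mutual_information",
    "scores_frame",
    "score_features",
    "select_features",
    "HRCTVFeatureSelector",
    "write_scores_report",
]


def anova_f(values: Sequence[float], labels: Sequence) -> float:
    """One-way ANOVA F score of one feature against a two-class label.

    F = between-class mean square / within-class mean square. A feature that
    is constant within every class and has equal class means (0/0) is
    defined to score 0.
    """
    x = np.asarray(values, dtype=float).reshape(-1, 1)
    y = np.asarray(labels)
    if len(np.unique(y)) != 2:
        raise ValueError("anova_f requires exactly 2 classes")
    for cls in np.unique(y):
        if (y == cls).sum() < 2:
            raise ValueError("anova_f requires >= 2 samples per class")
    with warnings.catch_warnings():
        # a constant feature triggers 0/0 chatter; the result is defined as 0
        warnings.simplefilter("ignore", RuntimeWarning)
        warnings.simplefilter("ignore", UserWarning)
        f, _ = f_classif(x, y)
    f = float(f[0])
    return 0.0 if np.isnan(f) else f


def mutual_information(
    values: Sequence[float],
    labels: Sequence,
    neighbors: int = 3,
    seed: int | None = 0,
) -> float:
    """Mutual information (nats) between a continuous feature and the class.

    Uses the k-nearest-neighbour estimator with seeded jitter for tie
    breaking; negative estimates are clamped to 0 (a constant feature scores
    exactly 0).
    """
    x = np.asarray(values, dtype=float).reshape(-1, 1)
    mi = mutual_info_classif(
        x, np.asarray(labels), n_neighbors=neighbors, random_state=seed
    )
    return float(max(mi[0], 0.0))


def _competition_ranks(primary: np.ndarray, tiebreak: np.ndarray) -> np.ndarray:
    """Rank descending by ``primary``; ties broken by ``tiebreak`` (descending),
    then by fixed feature order. Returns ranks 1..n (a permutation)."""
    n = len(primary)
    order = np.lexsort((np.arange(n), -tiebreak, -primary))
    ranks = np.empty(n, dtype=int)
    ranks[order] = np.arange(1, n + 1)
    return ranks


def score_features(
    X: pd.DataFrame | np.ndarray,
    y: Sequence,
    feature_names: Sequence[str] | None = None,
    mi_neighbors: int = 3,
    seed: int | None = 0,
) -> pd.DataFrame:
    """Score every feature by ANOVA F and mutual information.

    Returns a DataFrame indexed by feature name with columns ``f_score``,
    ``mi_score``, ``rank_f``, ``rank_mi`` (rank 1 = most informative; rank
    ties broken by f_score, then by the fixed feature order).
    """
    if isinstance(X, pd.DataFrame):
        feature_names = list(X.columns)
        Xv = X.to_numpy(dtype=float)
    else:
        Xv = np.asarray(X, dtype=float)
        if feature_names is None:
            feature_names = [f"feature_{i}" for i in range(Xv.shape[1])]
    y = np.asarray(y)
    f = np.array([anova_f(Xv[:, j], y) for j in range(Xv.shape[1])])
    mi = np.array(
        [
            mutual_information(Xv[:, j], y, neighbors=mi_neighbors, seed=seed)
            for j in range(Xv.shape[1])
        ]
    )
    return scores_frame(f, mi, feature_names)


def scores_frame(
    f_scores: Sequence[float],
    mi_scores: Sequence[float],
    feature_names: Sequence[str],
) -> pd.DataFrame:
    """Assemble a score table with both rankings from raw score arrays
    (rank ties broken by f_score, then by the fixed feature order)."""
    f = np.asarray(f_scores, dtype=float)
    mi = np.asarray(mi_scores, dtype=float)
    return pd.DataFrame(
        {
            "f_score": f,
            "mi_score": mi,
            "rank_f": _competition_ranks(f, mi),
            "rank_mi": _competition_ranks(mi, f),
        },
        index=pd.Index(feature_names, name="feature"),
    )


def select_features(
    scores: pd.DataFrame, k: int = 6, rule: str = "group"
) -> list[str]:
    """Reduce the feature set.

    rule="group" (the headline path) keeps the HR-CTV geometry-metric group
    — axis offset, lateral mean/max extent, vertical mean/max extent, and
    volume. rule="intersection" keeps features ranked in the top ``k`` under
    BOTH scores; if the intersection falls short of ``k`` a warning is
    emitted and it is topped up by f_score rank. Returned in the scores'
    feature order.
    """
    names = list(scores.index)
    if rule == "group":
        kept = [n for n in names if n in HRCTV_FEATURES]
        if not kept:
            raise ValueError("no HR-CTV geometry features present in scores")
        return kept
    if rule != "intersection":
        raise ValueError(f"unknown selection rule {rule!r}")
    if k > len(names):
        raise ValueError(f"k={k} exceeds the {len(names)} scored features")
    mask = (scores["rank_f"] <= k) & (scores["rank_mi"] <= k)
    kept = [n for n in names if mask.loc[n]]
    if len(kept) < k:
        warnings.warn(
            f"top-{k} intersection holds only {len(kept)} features; "
            "topping up by F-score rank",
            UserWarning,
        )
        extras = scores.loc[~scores.index.isin(kept)].sort_values("rank_f").index
        kept = kept + list(extras[: k - len(kept)])
        kept = [n for n in names if n in kept]
    return kept


class HRCTVFeatureSelector(SelectorMixin, BaseEstimator):
    """Sklearn selector applying the univariate reduction.

    Parameters
    ----------
    rule : {"group", "intersection"}
        "group" (default) retains the six HR-CTV geometry metrics;
        "intersection" retains the top-``k`` features under both the ANOVA F
        and mutual-information rankings.
    k : int
        Target feature count for the intersection rule.
    mi_neighbors : int
        Neighbour count of the mutual-information estimator.
    random_state : int or None
        Seed for the estimator's tie-breaking jitter.

    Attributes
    ----------
    scores_ : DataFrame
        Per-feature f_score / mi_score / ranks.
    selected_features_ : list of str
    """

    def __init__(
        self,
        rule: str = "group",
        k: int = 6,
        mi_neighbors: int = 3,
        random_state: int | None = 0,
    ):
        self.rule = rule
        self.k = k
        self.mi_neighbors = mi_neighbors
        self.random_state = random_state

    def fit(self, X, y) -> "HRCTVFeatureSelector":
        if isinstance(X, pd.DataFrame):
            self.feature_names_in_ = np.asarray(X.columns, dtype=object)
            names = list(X.columns)
        else:
            names = None
        self.scores_ = score_features(
            X, y, feature_names=names,
            mi_neighbors=self.mi_neighbors, seed=self.random_state,
        )
        self.n_features_in_ = len(self.scores_)
        self.selected_features_ = select_features(self.scores_, k=self.k, rule=self.rule)
        self._mask = np.asarray(self.scores_.index.isin(self.selected_features_))
        return self

    def _get_support_mask(self) -> np.ndarray:
        check_is_fitted(self, "_mask")
        return self._mask

    def transform(self, X):
        check_is_fitted(self, "_mask")
        if isinstance(X, pd.DataFrame):
            return X.loc[:, self.selected_features_]
        return np.asarray(X)[:, self._mask]


def write_scores_report(scores: pd.DataFrame, path: str | Path) -> None:
    """Write the score table as CSV (Feature, F-Score, Mutual Information,
    plus both ranks), using display names where features are canonical."""
    out = pd.DataFrame(
        {
            "Feature": [DISPLAY_NAMES.get(n, n) for n in scores.index],
            "F-Score": scores["f_score"].round(4).to_numpy(),
            "Mutual Information": scores["mi_score"].round(4).to_numpy(),
            "F-Score Rank": scores["rank_f"].to_numpy(),
            "Mutual Information Rank": scores["rank_mi"].to_numpy(),
        }
    )
    out.to_csv(path, index=False)
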