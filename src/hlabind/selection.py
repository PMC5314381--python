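"""Mutual-information feature ranking (MaxRel, mRMR) and incremental
feature selection (IFS).

Continuous descriptors are discretized into three states split at
mean +/- 0.5 sd (the classic mRMR default) before any mutual-information
computation. Relevance of a feature is its MI with the class label;
redundancy is its mean MI with the features already selected. The mRMR
list is built greedily: the first pick is the most relevant feature, each
later pick maximizes relevance minus mean redundancy. IFS then evaluates
the nested prefixes S_1 c S_2 c ... of the ranked list with a
cross-validated classifier and picks the prefix with the largest Matthews
correlation coefficient (ties: the smallest prefix).

All ties anywhere break toward the smaller feature index / smaller set
size, so rankings and curves are exactly reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, clone

from .classifiers import NearestNeighborClassifier
from .metrics import ConfusionMatrix, acc, confusion, mcc, sn, sp, stratified_folds


def discretize(values) -> np.ndarray:
    """Map a real vector to 3 states split at mean - 0.5 sd and mean + 0.5 sd.

    States are 0 (below), 1 (middle, inclusive bounds), 2 (above). A
    constant vector collapses to the single middle state.
    """
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("cannot discretize an empty vector")
    if not np.all(np.isfinite(v)):
        raise ValueError("values must be finite")
    mu, sd = v.mean(), v.std()
    if sd == 0:
        return np.ones(v.size, dtype=np.int8)
    lo, hi = mu - 0.5 * sd, mu + 0.5 * sd
    return (np.int8(1) * ((v >= lo) & (v <= hi)) + np.int8(2) * (v > hi)).astype(np.int8)


def mutual_information(x, y) -> float:
    """Empirical plug-in mutual information between two state vectors, in bits.

    ``sum_{x,y} p(x,y) log2(p(x,y) / (p(x) p(y)))`` with 0 log 0 := 0.
    """
    x = np.asarray(x)
    y = np.asarray(y)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-d vectors of equal length")
    if x.size == 0:
        raise ValueError("vectors must be non-empty")
    _, xi = np.unique(x, return_inverse=True)
    _, yi = np.unique(y, return_inverse=True)
    nx, ny = xi.max() + 1, yi.max() + 1
    joint = np.bincount(xi * ny + yi, minlength=nx * ny).reshape(nx, ny) / x.size
    px = joint.sum(axis=1)
    py = joint.sum(axis=0)
    nz = joint > 0
    outer = px[:, None] * py[None, :]
    return float(np.sum(joint[nz] * np.log2(joint[nz] / outer[nz])))


def _mi_states(xi: np.ndarray, yi: np.ndarray, nx: int, ny: int) -> float:
    """MI for pre-encoded state vectors (internal fast path)."""
    joint = np.bincount(xi * ny + yi, minlength=nx * ny).reshape(nx, ny) / xi.size
    px = joint.sum(axis=1)
    py = joint.sum(axis=0)
    nz = joint > 0
    return float(np.sum(joint[nz] * np.log2(joint[nz] / (px[:, None] * py[None, :])[nz])))


@dataclass
class RankedFeatureList:
    """Feature indices in ranked order with per-rank scores.

    ``order`` is a permutation of ``0..n_features-1`` when the ranking is
    complete; a greedy ranking truncated at ``k`` picks carries only the
    first ``k`` entries (``complete`` is False then).
    """

    criterion: str  # "MaxRel" | "mRMR"
    order: np.ndarray
    scores: np.ndarray
    n_features: int
    names: list[str] | None = None

    @property
    def complete(self) -> bool:
        return len(self.order) == self.n_features

    def top(self, k: int) -> np.ndarray:
        if k > len(self.order):
            raise ValueError(f"only {len(self.order)} ranks available, asked for {k}")
        return self.order[:k]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "rank": np.arange(1, len(self.order) + 1),
                "feature_index": self.order,
                "criterion": self.criterion,
                "score": self.scores,
            }
        )
        if self.names is not None:
            df.insert(2, "feature_name", [self.names[i] for i in self.order])
        return df


def _validate_xy(X, y):
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if X.ndim != 2:
        raise ValueError("X must be 2-d")
    if len(y) != X.shape[0]:
        raise ValueError("X and y length mismatch")
    if len(np.unique(y)) != 2:
        raise ValueError("labels must be binary (both classes present)")
    return X, y


def _discretize_matrix(X: np.ndarray) -> np.ndarray:
    return np.column_stack([discretize(X[:, j]) for j in range(X.shape[1])])


def maxrel_rank(X, y, names: list[str] | None = None) -> RankedFeatureList:
    """Rank features by mutual information with the class label alone."""
    X, y = _validate_xy(X, y)
    S = _discretize_matrix(X)
    _, yi = np.unique(y, return_inverse=True)
    rel = np.array([_mi_states(S[:, j], yi, 3, 2) for j in range(X.shape[1])])
    order = np.argsort(-rel, kind="stable")  # stable: ties keep smaller index first
    return RankedFeatureList("MaxRel", order, rel[order], X.shape[1], names)


def mrmr_rank(
    X, y, names: list[str] | None = None, k: int | None = None
) -> RankedFeatureList:
    """Greedy minimum-redundancy maximum-relevance feature ranking.

    The first pick is the MaxRel top feature; each subsequent pick maximizes
    ``MI(f, y) - mean_{s in selected} MI(f, s)``. ``k`` truncates the greedy
    run after ``k`` picks (the full permutation is the default).
    """
    X, y = _validate_xy(X, y)
    D = X.shape[1]
    k = D if k is None else min(k, D)
    S = _discretize_matrix(X)
    _, yi = np.unique(y, return_inverse=True)
    rel = np.array([_mi_states(S[:, j], yi, 3, 2) for j in range(D)])

    order = np.empty(k, dtype=int)
    scores = np.empty(k)
    remaining = np.ones(D, dtype=bool)
    red_sum = np.zeros(D)

    first = int(np.argmax(rel))  # argmax takes the smallest index on ties
    order[0], scores[0] = first, rel[first]
    remaining[first] = False
    for step in range(1, k):
        last = order[step - 1]
        for j in np.flatnonzero(remaining):
            red_sum[j] += _mi_states(S[:, j], S[:, last], 3, 3)
        crit = np.where(remaining, rel - red_sum / step, -np.inf)
        pick = int(np.argmax(crit))
        order[step], scores[step] = pick, crit[pick]
        remaining[pick] = False
    return RankedFeatureList("mRMR", order, scores, D, names)


def ifs_sets(ranked: RankedFeatureList) -> list[np.ndarray]:
    """Nested prefix sets S_1 c S_2 c ... of the ranked feature list."""
    return [ranked.order[:i] for i in range(1, len(ranked.order) + 1)]


@dataclass
class IFSResult:
    """Cross-validated metric curve over nested feature-set sizes."""

    curve: pd.DataFrame = field(repr=False)  # columns: size, SN, SP, ACC, MCC
    optimal_size: int = 0
    optimal_mcc: float = 0.0


def select_optimal(curve: pd.DataFrame) -> tuple[int, float]:
    """Pick (size, MCC) maximizing MCC; ties go to the smallest size."""
    if len(curve) == 0:
        raise ValueError("empty IFS curve")
    best = int(np.argmax(curve["MCC"].to_numpy()))  # first occurrence wins
    return int(curve["size"].iloc[best]), float(curve["MCC"].iloc[best])


def _pool_metrics(cms: list[ConfusionMatrix]) -> tuple[float, float, float, float]:
    pooled = cms[0]
    for c in cms[1:]:
        pooled = pooled + c
    return sn(pooled), sp(pooled), acc(pooled), mcc(pooled)


def evaluate_ifs(
    X,
    y,
    ranked: RankedFeatureList,
    estimator=None,
    k: int = 10,
    seed: int = 0,
    max_features: int | None = None,
) -> IFSResult:
    """Cross-validated IFS curve over the nested prefixes of a ranked list.

    For every prefix S_i, a stratified ``k``-fold cross-validation (seeded,
    deterministic) is run, fold predictions are pooled into one confusion
    matrix, and SN/SP/ACC/MCC are computed from the pool. The optimum is the
    prefix with maximal MCC (ties: smallest prefix).

    A 1-nearest-neighbour estimator takes a fast path that updates squared
    distances incrementally as features are added; results are identical to
    refitting per prefix.

    Parameters
    ----------
    max_features : int or None
        Evaluate only the first ``max_features`` prefixes (default: the full
        ranked list).
    """
    X, y = _validate_xy(X, y)
    estimator = estimator if estimator is not None else NearestNeighborClassifier()
    depth = len(ranked.order) if max_features is None else min(max_features, len(ranked.order))
    folds = stratified_folds(y, k=k, seed=seed)

    # predictions[size-1][fold] -> (y_true, y_pred)
    cms = [[] for _ in range(depth)]
    fast = type(estimator) is NearestNeighborClassifier
    for f in range(k):
        test = folds == f
        train = ~test
        ytr, yte = y[train], y[test]
        if len(np.unique(ytr)) < 2 or len(np.unique(yte)) < 2:
            raise ValueError(
                f"fold {f} lacks both classes; use a smaller k"
            )
        if fast:
            Xtr, Xte = X[train], X[test]
            sq = np.zeros((Xte.shape[0], Xtr.shape[0]))
            for i in range(depth):
                col = ranked.order[i]
                d = Xte[:, col][:, None] - Xtr[:, col][None, :]
                sq += d * d
                pred = ytr[np.argmin(sq, axis=1)]
                cms[i].append(confusion(yte, pred))
        else:
            for i in range(depth):
                cols = ranked.order[: i + 1]
                est = clone(estimator)
                est.fit(X[np.ix_(train, cols)], ytr)
                pred = est.predict(X[np.ix_(test, cols)])
                cms[i].append(confusion(yte, pred))

    rows = []
    for i in range(depth):
        s, p, a, m = _pool_metrics(cms[i])
        rows.append((i + 1, s, p, a, m))
    curve = pd.DataFrame(rows, columns=["size", "SN", "SP", "ACC", "MCC"])
    size, best = select_optimal(curve)
    return IFSResult(curve=curve, optimal_size=size, optimal_mcc=best)


class MRMRRanker(BaseEstimator):
    """Scikit-learn style wrapper around MaxRel / mRMR feature ranking.

    Parameters
    ----------
    criterion : {"mrmr", "maxrel"}
        Ranking criterion.
    k : int or None
        Number of greedy picks to compute (mRMR only); ``None`` ranks all
        features. ``transform`` selects the top ``k`` (or all ranked)
        columns.

    Attributes
    ----------
    ranking_ : RankedFeatureList
    """

    def __init__(self, criterion: str = "mrmr", k: int | None = None):
        self.criterion = criterion
        self.k = k

    def fit(self, X, y):
        if self.criterion == "mrmr":
            self.ranking_ = mrmr_rank(X, y, k=self.k)
        elif self.criterion == "maxrel":
            self.ranking_ = maxrel_rank(X, y)
        else:
            raise ValueError(f"unknown criterion {self.criterion!r}")
        self.n_features_in_ = np.asarray(X).shape[1]
        return self

    def transform(self, X):
        X = np.asarray(X)
        k = self.k if self.k is not None else len(self.ranking_.order)
        return X[:, self.ranking_.top(k)]


class IncrementalFeatureSelector(BaseEstimator):
    """IFS model selection over a ranked feature list.

    ``fit`` ranks the features (mRMR unless a ranking is supplied), runs
    seeded stratified cross-validation over the nested prefixes, and records
    the metric curve plus the MCC-optimal prefix.

    Parameters
    ----------
    estimator : classifier, default 1-nearest-neighbour
    cv : int, default 10
        Stratified fold count.
    random_state : int, default 0
        Fold-assignment seed (also passed to an internally built ranking).
    max_features : int or None
        Evaluation depth along the ranked list.

    Attributes
    ----------
    ranking_ : RankedFeatureList
    curve_ : pandas.DataFrame with columns size, SN, SP, ACC, MCC
    optimal_size_ : int
    optimal_mcc_ : float
    support_ : boolean mask of the optimal feature subset
    """

    def __init__(
        self,
        estimator=None,
        cv: int = 10,
        random_state: int = 0,
        max_features: int | None = None,
    ):
        self.estimator = estimator
        self.cv = cv
        self.random_state = random_state
        self.max_features = max_features

    def fit(self, X, y, ranking: RankedFeatureList | None = None):
        X = np.asarray(X, dtype=float)
        if ranking is None:
            ranking = mrmr_rank(X, y, k=self.max_features)
        self.ranking_ = ranking
        res = evaluate_ifs(
            X, y, ranking,
            estimator=self.estimator,
            k=self.cv,
            seed=self.random_state,
            max_features=self.max_features,
        )
        self.curve_ = res.curve
        self.optimal_size_ = res.optimal_size
        self.optimal_mcc_ = res.optimal_mcc
        self.support_ = np.zeros(ranking.n_features, dtype=bool)
        self.support_[ranking.top(self.optimal_size_)] = True
        return self

    def transform(self, X):
        return np.asarray(X)[:, self.support_]

    def get_support(self, indices: bool = False):
        return np.flatnonzero(self.support_) if indices else self.support_
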