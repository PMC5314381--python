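"""Classifier backends behind a common scikit-learn estimator contract.

Two algorithms are implemented natively because their exact semantics matter
to the pipeline:

* :class:`NearestNeighborClassifier` — 1-nearest-neighbour by Euclidean
  distance with a fixed tie rule (smallest training-row index), and no
  training step beyond storing the data;
* :class:`DaggingClassifier` — an ensemble of base classifiers trained on
  disjoint subsets sampled without replacement, combined by majority vote.

Random forest and linear SVM are delegated to scikit-learn via
:func:`backend_rf` and :func:`backend_svm`.
"""

from __future__ import annotations

import logging

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin, clone
from sklearn.ensemble import RandomForestClassifier
from sklearn.svm import SVC
from sklearn.utils.validation import check_X_y, check_array

logger = logging.getLogger(__name__)


class NearestNeighborClassifier(BaseEstimator, ClassifierMixin):
    """1-NN classification by Euclidean distance.

    There is no training process: ``fit`` stores the data and ``predict``
    assigns each query the label of its nearest training sample. Distance
    ties are broken by the smallest training-row index, making predictions
    fully deterministic.
    """

    def fit(self, X, y):
        X, y = check_X_y(X, y)
        self.X_ = X
        self.y_ = np.asarray(y)
        self.classes_ = np.unique(self.y_)
        self.n_features_in_ = X.shape[1]
        return self

    def predict(self, X):
        X = check_array(X)
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"query has {X.shape[1]} features, training data has "
                f"{self.n_features_in_}"
            )
        # squared Euclidean distances; argmin returns the first (smallest
        # index) minimiser, which is the tie rule.
        sq = (
            (X * X).sum(axis=1)[:, None]
            - 2.0 * X @ self.X_.T
            + (self.X_ * self.X_).sum(axis=1)[None, :]
        )
        return self.y_[np.argmin(sq, axis=1)]


class DaggingClassifier(BaseEstimator, ClassifierMixin):
    """Disjoint-subset ensemble ("dagging") with majority voting.

    The N training samples are partitioned (without replacement) into
    ``n_subsets`` disjoint subsets of ``floor(N / n_subsets)`` samples each,
    one base classifier is trained per subset, and queries are classified by
    majority vote. ``n_subsets`` must be odd so the two-class vote cannot
    tie when all members vote; if a subset lacks both classes it is dropped
    from the vote (logged), and an even split then falls back to the
    majority training class.

    Parameters
    ----------
    n_subsets : int, default 9
        Number of disjoint subsets (odd).
    base_estimator : estimator or None
        Classifier cloned per subset; default 1-nearest-neighbour.
    random_state : int, default 0
        Seed for the subset partition.
    """

    def __init__(self, n_subsets: int = 9, base_estimator=None, random_state: int = 0):
        self.n_subsets = n_subsets
        self.base_estimator = base_estimator
        self.random_state = random_state

    def fit(self, X, y):
        X, y = check_X_y(X, y)
        if self.n_subsets % 2 == 0:
            raise ValueError(f"n_subsets must be odd, got {self.n_subsets}")
        n = len(y)
        if self.n_subsets > n:
            raise ValueError(
                f"n_subsets={self.n_subsets} exceeds the {n} training samples"
            )
        per = n // self.n_subsets  # m * per <= N by construction
        rng = np.random.default_rng(self.random_state)
        order = rng.permutation(n)
        base = self.base_estimator if self.base_estimator is not None else NearestNeighborClassifier()
        self.subsets_ = []
        self.estimators_ = []
        self.classes_ = np.unique(y)
        self._y_majority = self.classes_[np.argmax([np.sum(y == c) for c in self.classes_])]
        for m in range(self.n_subsets):
            idx = np.sort(order[m * per : (m + 1) * per])
            if len(np.unique(y[idx])) < 2:
                logger.warning("dagging subset %d is single-class; dropped from the vote", m)
                continue
            est = clone(base)
            est.fit(X[idx], y[idx])
            self.subsets_.append(idx)
            self.estimators_.append(est)
        if not self.estimators_:
            raise ValueError("no dagging subset contained both classes; enlarge the data")
        self.n_features_in_ = X.shape[1]
        return self

    def predict(self, X):
        X = check_array(X)
        votes = np.stack([est.predict(X) for est in self.estimators_])
        out = np.empty(X.shape[0], dtype=votes.dtype)
        for j in range(X.shape[0]):
            vals, counts = np.unique(votes[:, j], return_counts=True)
            top = counts.max()
            winners = vals[counts == top]
            if len(winners) > 1:
                # even effective vote after dropped members: majority class
                logger.warning("dagging vote tie; predicting majority class")
                out[j] = self._y_majority
            else:
                out[j] = winners[0]
        return out


def backend_rf(random_state: int = 0, **hyperparameters) -> RandomForestClassifier:
    """Random-forest backend: bagging + random sub-feature selection, 100 trees."""
    return RandomForestClassifier(
        n_estimators=hyperparameters.pop("n_estimators", 100),
        random_state=random_state,
        **hyperparameters,
    )


def backend_svm(random_state: int = 0, **hyperparameters) -> SVC:
    """Linear-kernel SVM backend (C = 1)."""
    return SVC(
        kernel=hyperparameters.pop("kernel", "linear"),
        C=hyperparameters.pop("C", 1.0),
        random_state=random_state,
        **hyperparameters,
    )


#: Registry used by the command line and the IFS runner.
BACKENDS = {
    "nna": lambda seed=0: NearestNeighborClassifier(),
    "dagging": lambda seed=0: DaggingClassifier(random_state=seed),
    "rf": backend_rf,
    "svm": backend_svm,
}


def nna_fit_predict(train_X, train_y, query_X):
    """Functional 1-NN: label each query by its Euclidean-nearest training row."""
    return NearestNeighborClassifier().fit(train_X, train_y).predict(query_X)
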