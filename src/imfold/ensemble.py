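"""A balanced random forest for heavily imbalanced binary problems.

Genome-wide folded iMs are outnumbered by unfolded C-rich sequences by
roughly 1:83, which drives an ordinary forest toward the majority class.
The balanced variant draws, for every tree, a bootstrap sample of the
minority class together with an equally sized random undersample of the
majority class, so each tree trains on a 1:1 problem while the ensemble
still sees most of the majority data.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin, clone
from sklearn.tree import DecisionTreeClassifier
from sklearn.utils.validation import check_is_fitted, check_X_y, check_array


class BalancedRandomForestClassifier(ClassifierMixin, BaseEstimator):
    """Forest of CARTs, each fit on a class-balanced bootstrap.

    Parameters mirror the scikit-learn forest surface where they matter:
    ``n_estimators`` trees, ``max_depth``/``min_samples_leaf`` growth
    limits, ``max_features`` split subsampling ("sqrt" by default), and a
    mandatory ``random_state`` for reproducibility.
    """

    def __init__(
        self,
        n_estimators: int = 100,
        max_depth: int | None = None,
        min_samples_leaf: int = 1,
        max_features: str | int | float = "sqrt",
        random_state: int | None = None,
    ):
        self.n_estimators = n_estimators
        self.max_depth = max_depth
        self.min_samples_leaf = min_samples_leaf
        self.max_features = max_features
        self.random_state = random_state

    def fit(self, X, y):
        X, y = check_X_y(X, y)
        self.classes_, y_enc = np.unique(y, return_inverse=True)
        if len(self.classes_) != 2:
            raise ValueError(
                f"balanced forest is binary; got {len(self.classes_)} class(es)"
            )
        rng = np.random.default_rng(self.random_state)
        counts = np.bincount(y_enc)
        minority = int(np.argmin(counts))
        n_min = int(counts[minority])
        idx_by_class = [np.flatnonzero(y_enc == k) for k in (0, 1)]

        base = DecisionTreeClassifier(
            max_depth=self.max_depth,
            min_samples_leaf=self.min_samples_leaf,
            max_features=self.max_features,
        )
        self.estimators_ = []
        for _ in range(self.n_estimators):
            sample = np.concatenate(
                [rng.choice(idx_by_class[k], size=n_min, replace=True) for k in (0, 1)]
            )
            tree = clone(base)
            tree.set_params(random_state=int(rng.integers(0, 2**31 - 1)))
            tree.fit(X[sample], y_enc[sample])
            self.estimators_.append(tree)
        self.n_features_in_ = X.shape[1]
        return self

    def predict_proba(self, X):
        check_is_fitted(self, "estimators_")
        X = check_array(X)
        proba = np.zeros((X.shape[0], 2))
        for tree in self.estimators_:
            p = tree.predict_proba(X)
            # a tree bootstrap always contains both classes, so p has 2 cols
            proba += p
        return proba / len(self.estimators_)

    def predict(self, X):
        return self.classes_[np.argmax(self.predict_proba(X), axis=1)]

    @property
    def feature_importances_(self):
        check_is_fitted(self, "estimators_")
        imp = np.mean([t.feature_importances_ for t in self.estimators_], axis=0)
        s = imp.sum()
        return imp / s if s > 0 else imp
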