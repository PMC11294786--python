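"""scikit-learn compatible wrapper around the unregularized logistic classifier.

The study's classification step — unregularized maximum-likelihood logistic
regression scored at a probability cutoff — exposed with the estimator API so
it drops into sklearn pipelines, cross-validation, and model selection.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.multiclass import unique_labels
from sklearn.utils.validation import check_array, check_is_fitted, check_X_y

from .diagnostics import LogisticModel, fit_logistic

__all__ = ["NocturnalVitalsClassifier"]


class NocturnalVitalsClassifier(ClassifierMixin, BaseEstimator):
    """Unregularized binary logistic regression with a fixed decision cutoff.

    Parameters
    ----------
    threshold : probability above (or at) which the positive class is
        predicted; the study convention is 0.5.
    max_iter, tol : Newton/IRLS iteration cap and coefficient-change tolerance.

    Attributes
    ----------
    classes_ : the two class labels, sorted; the second is treated positive.
    coef_, intercept_ : fitted log-odds coefficients, shape (1, n_features)/(1,).
    converged_ : whether the Newton iteration met its tolerance.
    """

    def __init__(self, threshold: float = 0.5, max_iter: int = 100, tol: float = 1e-8):
        self.threshold = threshold
        self.max_iter = max_iter
        self.tol = tol

    def fit(self, X, y):
        X, y = check_X_y(X, y, dtype=float)
        self.classes_ = unique_labels(y)
        if len(self.classes_) != 2:
            raise ValueError("NocturnalVitalsClassifier is strictly binary")
        y_bin = (y == self.classes_[1]).astype(int)
        model: LogisticModel = fit_logistic(
            pd.DataFrame(X), y_bin, max_iter=self.max_iter, tol=self.tol
        )
        self.model_ = model
        self.coef_ = model.coefficients.reshape(1, -1)
        self.intercept_ = np.array([model.intercept])
        self.converged_ = model.converged
        self.n_features_in_ = X.shape[1]
        return self

    def decision_function(self, X):
        check_is_fitted(self)
        X = check_array(X, dtype=float)
        return self.intercept_[0] + X @ self.coef_[0]

    def predict_proba(self, X):
        eta = self.decision_function(X)
        p = 1.0 / (1.0 + np.exp(-eta))
        return np.column_stack([1.0 - p, p])

    def predict(self, X):
        p = self.predict_proba(X)[:, 1]
        return np.where(p >= self.threshold, self.classes_[1], self.classes_[0])
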