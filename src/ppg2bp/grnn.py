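"""Generalized regression neural network (Nadaraya-Watson kernel regressor).

A GRNN is a lazy learner: "training" stores the sample matrices, and a
prediction is the Gaussian-kernel-weighted average of the training
targets,

    y_j(x) = sum_i w_ij * exp(-||x - mu_i||^2 / (2 delta^2))
             / sum_i exp(-||x - mu_i||^2 / (2 delta^2))

with one shared pattern layer (the weights do not depend on the output
component j), a summation layer (S_D and the S_Nj), and delta the single
smoothing hyperparameter.

With the default delta = 0.001 on raw harmonic features the raw
exponentials underflow to zero for every training sample, making the
ratio 0/0; the implementation subtracts the per-query maximum exponent
before exponentiating (softmax-style), which is algebraically identical
and keeps the weights well defined at any delta. In that small-delta
regime the model behaves as a nearest-neighbor regressor; exact distance
ties average the tied targets symmetrically.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial.distance import cdist
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_array, check_is_fitted, validate_data


class GRNNRegressor(RegressorMixin, BaseEstimator):
    """Gaussian-kernel regression with stored training data.

    Parameters
    ----------
    delta : float, default=0.001
        Kernel smoothing width. Must be positive. Small values give
        nearest-neighbor behavior; large values shrink every prediction
        toward the target column means.
    standardize : bool, default=False
        If True, z-score the inputs using training statistics before
        computing kernel distances. Off by default: the canonical setup
        applies delta to raw harmonic features (an effectively
        nearest-neighbor regime). When enabled, delta is interpreted on
        the standardized scale.

    Attributes
    ----------
    X_train_ : ndarray of shape (n_samples, n_features)
        Stored (possibly standardized) training inputs -- the pattern
        layer; the node count equals the number of training samples.
    Y_train_ : ndarray of shape (n_samples, n_outputs)
        Stored training targets.
    mean_, scale_ : ndarray of shape (n_features,)
        Standardization parameters (identity when standardize=False).
    """

    def __init__(self, delta: float = 0.001, standardize: bool = False):
        self.delta = delta
        self.standardize = standardize

    def fit(self, X, y):
        """Store the training set (no iterative optimization occurs)."""
        if self.delta <= 0:
            raise ValueError(f"delta must be positive, got {self.delta}")
        X, y = validate_data(self, X, y, multi_output=True, y_numeric=True)
        Y = np.asarray(y, dtype=float)
        self._y_1d_ = Y.ndim == 1
        if self._y_1d_:
            Y = Y[:, None]
        if not np.all(np.isfinite(Y)):
            raise ValueError("training targets contain non-finite entries")
        if self.standardize:
            self.mean_ = X.mean(axis=0)
            scale = X.std(axis=0)
            scale[scale == 0] = 1.0
            self.scale_ = scale
        else:
            self.mean_ = np.zeros(X.shape[1])
            self.scale_ = np.ones(X.shape[1])
        self.X_train_ = (X - self.mean_) / self.scale_
        self.Y_train_ = Y
        return self

    def _weights(self, X: np.ndarray) -> np.ndarray:
        sqdist = cdist(X, self.X_train_, metric="sqeuclidean")
        exponent = -sqdist / (2.0 * self.delta**2)
        exponent -= exponent.max(axis=1, keepdims=True)
        w = np.exp(exponent)
        return w / w.sum(axis=1, keepdims=True)

    def predict(self, X):
        """Kernel-weighted average of training targets for each query row."""
        check_is_fitted(self, "X_train_")
        X = check_array(X, ensure_min_samples=0)
        if X.shape[1] != self.X_train_.shape[1]:
            raise ValueError(
                f"query has {X.shape[1]} features; model was fitted with "
                f"{self.X_train_.shape[1]}"
            )
        if X.shape[0] == 0:
            out = np.empty((0, self.Y_train_.shape[1]))
        else:
            out = self._weights((X - self.mean_) / self.scale_) @ self.Y_train_
        return out.ravel() if getattr(self, "_y_1d_", False) else out


def fit(X, Y, delta: float = 0.001, standardize: bool = False) -> GRNNRegressor:
    """Build and fit a :class:`GRNNRegressor` (fit = store)."""
    return GRNNRegressor(delta=delta, standardize=standardize).fit(X, Y)


def predict(model: GRNNRegressor, x: np.ndarray) -> np.ndarray:
    """Predict the target vector for a single query point."""
    x = np.asarray(x, dtype=float)
    if x.ndim != 1:
        raise ValueError("predict expects a single 1-D query; use predict_batch")
    return np.asarray(model.predict(x[None, :]))[0]


def predict_batch(model: GRNNRegressor, X: np.ndarray) -> np.ndarray:
    """Row-wise prediction; identical results to the scalar path."""
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X.reshape(0, model.X_train_.shape[1]) if X.size == 0 else X[None, :]
    return np.asarray(model.predict(X))
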