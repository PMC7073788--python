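"""Calibration/prediction split and the three conventional classifiers.

Split rule: within each cultivar's acquisition order, every third sample
starting from sample 2 goes to the prediction set (so 59 samples per
cultivar split 39 calibration / 20 prediction).

Hyperparameter searches are exhaustive over the printed grids — SVM cost C
and RBF width gamma over powers of two 2^-8..2^8, RBF-network spread over
1..100 step 1, ELM hidden-neuron count over 1..n_calibration — scored by
5-fold cross-validated accuracy on the calibration set only, ties broken
toward the first (smallest) grid point.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

__all__ = [
    "SplitIndices",
    "split_cal_pred",
    "RBFKernelSVM",
    "RBFNetworkClassifier",
    "ELMClassifier",
    "train_svm",
    "train_rbfnn",
    "train_elm",
    "predict_class",
]

# Gaussian RBF bias so that activation = 0.5 when the distance equals the
# spread (the convention that makes "spread" a half-activation radius).
RBF_BIAS = 0.8326


@dataclass(frozen=True)
class SplitIndices:
    """Row indices (0-based, into the class-blocked dataset order)."""

    calibration: np.ndarray
    prediction: np.ndarray

    def __post_init__(self):
        inter = np.intersect1d(self.calibration, self.prediction)
        if inter.size:
            raise ValueError("calibration and prediction sets overlap")


def split_cal_pred(n_per_class: int, n_classes: int = 3) -> SplitIndices:
    """Every third sample, starting from sample 2, is held out for
    prediction — applied within each class block independently."""
    if n_per_class < 2:
        raise ValueError("need at least 2 samples per class")
    if n_classes < 1:
        raise ValueError("need at least one class")
    cal, pred = [], []
    for c in range(n_classes):
        offset = c * n_per_class
        for pos in range(1, n_per_class + 1):       # 1-based within class
            (pred if (pos - 2) % 3 == 0 and pos >= 2 else cal).append(
                offset + pos - 1)
    return SplitIndices(calibration=np.array(cal, dtype=int),
                        prediction=np.array(pred, dtype=int))


def _check_Xy(X, y):
    X = np.asarray(X, dtype=float)
    y = np.asarray(y).ravel()
    if X.ndim != 2 or len(y) != X.shape[0]:
        raise ValueError("X must be 2-D with one label per row")
    if np.unique(y).size < 2:
        raise ValueError("calibration set must contain at least two classes")
    return X, y


def _cv_splits(y: np.ndarray, n_folds: int) -> list[tuple[np.ndarray, np.ndarray]]:
    skf = StratifiedKFold(n_splits=n_folds, shuffle=False)
    return list(skf.split(np.zeros((len(y), 1)), y))


class RBFKernelSVM(BaseEstimator, ClassifierMixin):
    """RBF-kernel SVM with an exhaustive power-of-two (C, gamma) grid.

    Multi-class handling is one-vs-one voting (libsvm's native scheme).  The
    Gram matrix is computed once per gamma and reused across folds and C
    values, which makes the 17 x 17 grid cheap even on full spectra.
    """

    def __init__(self, exp_min: int = -8, exp_max: int = 8, cv: int = 5):
        self.exp_min = exp_min
        self.exp_max = exp_max
        self.cv = cv

    @property
    def grid_(self) -> list[tuple[float, float]]:
        exps = range(self.exp_min, self.exp_max + 1)
        return [(2.0**i, 2.0**j) for i in exps for j in exps]

    def fit(self, X, y):
        X, y = _check_Xy(X, y)
        self.n_features_in_ = X.shape[1]
        d2 = cdist(X, X, "sqeuclidean")
        splits = _cv_splits(y, self.cv)
        exps = list(range(self.exp_min, self.exp_max + 1))
        best = (-1.0, None)
        for i in exps:
            c_val = 2.0**i
            for j in exps:
                g_val = 2.0**j
                K = np.exp(-g_val * d2)
                correct = 0
                for tr, te in splits:
                    clf = SVC(C=c_val, kernel="precomputed")
                    clf.fit(K[np.ix_(tr, tr)], y[tr])
                    correct += np.sum(clf.predict(K[np.ix_(te, tr)]) == y[te])
                acc = correct / len(y)
                if acc > best[0]:       # strict: ties keep the first pair
                    best = (acc, (c_val, g_val))
        self.C_, self.gamma_ = best[1]
        self.cv_accuracy_ = best[0]
        self.X_fit_ = X
        K = np.exp(-self.gamma_ * d2)
        self.svc_ = SVC(C=self.C_, kernel="precomputed").fit(K, y)
        return self

    def predict(self, X):
        X = np.asarray(X, dtype=float)
        if X.shape[1] != self.n_features_in_:
            raise ValueError("feature count differs from fit")
        K = np.exp(-self.gamma_ * cdist(X, self.X_fit_, "sqeuclidean"))
        return self.svc_.predict(K)


class RBFNetworkClassifier(BaseEstimator, ClassifierMixin):
    """Exact-design radial basis function network.

    One Gaussian hidden unit per calibration sample (centres = samples),
    activation exp(-(RBF_BIAS * ||x - c|| / spread)^2); the linear output
    layer (one response per class, plus bias) is solved by least squares on
    one-hot targets, and the class is the argmax response.  Only the spread
    is tuned (grid 1..100, 5-fold CV accuracy, ties toward the smallest).
    """

    def __init__(self, spread_min: int = 1, spread_max: int = 100,
                 cv: int = 5, ridge: float = 1e-8):
        self.spread_min = spread_min
        self.spread_max = spread_max
        self.cv = cv
        self.ridge = ridge

    @staticmethod
    def _design(dist: np.ndarray, spread: float) -> np.ndarray:
        H = np.exp(-((RBF_BIAS / spread) * dist) ** 2)
        return np.hstack([H, np.ones((H.shape[0], 1))])

    def _solve(self, H: np.ndarray, T: np.ndarray) -> np.ndarray:
        if self.ridge_used_:
            A = H.T @ H + self.ridge * np.eye(H.shape[1])
            return np.linalg.solve(A, H.T @ T)
        return np.linalg.lstsq(H, T, rcond=None)[0]

    def fit(self, X, y):
        X, y = _check_Xy(X, y)
        self.n_features_in_ = X.shape[1]
        self.classes_ = np.unique(y)
        T = (y[:, None] == self.classes_[None, :]).astype(float)
        dist = cdist(X, X)
        self.ridge_used_ = bool(
            np.any(dist[~np.eye(len(y), dtype=bool)] < 1e-12))
        if self.ridge_used_:
            warnings.warn("duplicate calibration samples; using ridge-"
                          "regularised output-layer solve", stacklevel=2)
        splits = _cv_splits(y, self.cv)
        spreads = range(self.spread_min, self.spread_max + 1)
        best = (-1.0, None)
        for spread in spreads:
            correct = 0
            for tr, te in splits:
                W = self._solve(self._design(dist[np.ix_(tr, tr)], spread),
                                T[tr])
                pred = self._design(dist[np.ix_(te, tr)], spread) @ W
                correct += np.sum(self.classes_[pred.argmax(axis=1)] == y[te])
            acc = correct / len(y)
            if acc > best[0]:
                best = (acc, spread)
        self.spread_ = float(best[1])
        self.cv_accuracy_ = best[0]
        self.centers_ = X
        self.weights_ = self._solve(self._design(dist, self.spread_), T)
        return self

    def predict(self, X):
        X = np.asarray(X, dtype=float)
        if X.shape[1] != self.n_features_in_:
            raise ValueError("feature count differs from fit")
        H = self._design(cdist(X, self.centers_), self.spread_)
        return self.classes_[(H @ self.weights_).argmax(axis=1)]


class ELMClassifier(BaseEstimator, ClassifierMixin):
    """Extreme learning machine: random input layer, closed-form output.

    Input weights and biases are drawn once, uniform on [-1, 1], from the
    seeded generator; hidden activations are logistic sigmoids; output
    weights are the Moore-Penrose least-squares solution onto one-hot
    targets.  The hidden-unit count is tuned over 1..n_calibration by 5-fold
    CV accuracy (the nested grids share the same random projection, so the
    search is deterministic and cheap); ties go to the smallest network.
    """

    def __init__(self, n_hidden_grid=None, cv: int = 5, random_state: int = 0):
        self.n_hidden_grid = n_hidden_grid
        self.cv = cv
        self.random_state = random_state

    @staticmethod
    def _sigmoid(z: np.ndarray) -> np.ndarray:
        return 1.0 / (1.0 + np.exp(-np.clip(z, -500, 500)))

    def fit(self, X, y):
        X, y = _check_Xy(X, y)
        self.n_features_in_ = X.shape[1]
        self.classes_ = np.unique(y)
        T = (y[:, None] == self.classes_[None, :]).astype(float)
        grid = (list(self.n_hidden_grid) if self.n_hidden_grid is not None
                else list(range(1, len(y) + 1)))
        if max(grid) > len(y):
            raise ValueError("hidden-unit count exceeds calibration size")
        h_max = max(grid)
        rng = np.random.default_rng(self.random_state)
        self.w_in_ = rng.uniform(-1.0, 1.0, size=(X.shape[1], h_max))
        self.bias_ = rng.uniform(-1.0, 1.0, size=h_max)
        H = self._sigmoid(X @ self.w_in_ + self.bias_)
        splits = _cv_splits(y, self.cv)
        best = (-1.0, None)
        for h in grid:
            correct = 0
            for tr, te in splits:
                beta = np.linalg.lstsq(H[np.ix_(tr, range(h))], T[tr],
                                       rcond=None)[0]
                pred = H[np.ix_(te, range(h))] @ beta
                correct += np.sum(self.classes_[pred.argmax(axis=1)] == y[te])
            acc = correct / len(y)
            if acc > best[0]:           # ties keep the smaller network
                best = (acc, h)
        self.n_hidden_ = int(best[1])
        self.cv_accuracy_ = best[0]
        Hh = H[:, :self.n_hidden_]
        self.condition_number_ = float(np.linalg.cond(Hh))
        self.beta_ = np.linalg.pinv(Hh) @ T
        return self

    def predict(self, X):
        X = np.asarray(X, dtype=float)
        if X.shape[1] != self.n_features_in_:
            raise ValueError("feature count differs from fit")
        H = self._sigmoid(X @ self.w_in_[:, :self.n_hidden_]
                          + self.bias_[:self.n_hidden_])
        return self.classes_[(H @ self.beta_).argmax(axis=1)]


# --- thin functional wrappers -------------------------------------------

def train_svm(Xcal, ycal, exp_min: int = -8, exp_max: int = 8) -> RBFKernelSVM:
    return RBFKernelSVM(exp_min=exp_min, exp_max=exp_max).fit(Xcal, ycal)


def train_rbfnn(Xcal, ycal, spread_min: int = 1,
                spread_max: int = 100) -> RBFNetworkClassifier:
    return RBFNetworkClassifier(spread_min=spread_min,
                                spread_max=spread_max).fit(Xcal, ycal)


def train_elm(Xcal, ycal, n_hidden_grid=None, seed: int = 0) -> ELMClassifier:
    return ELMClassifier(n_hidden_grid=n_hidden_grid,
                         random_state=seed).fit(Xcal, ycal)


def predict_class(model, X) -> np.ndarray:
    """Predict cultivar labels with any trained classifier."""
    return np.asarray(model.predict(X))
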