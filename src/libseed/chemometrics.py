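"""PCA overview, PLS1 regression core, RMSECV and iPLS region selection.

iPLS (interval partial least squares) splits the spectrum into k equidistant
subintervals (k scanned over a range, default 10..30), fits a local PLS1
model per subinterval with 1..15 latent variables, scores each by the root
mean squared error of cross-validation (RMSECV), and selects the subinterval
whose best local model has the lowest RMSECV overall — also reporting the
full-spectrum (global) PLS model for comparison.  Class labels enter the
regression as the numeric codes 1, 2, 3.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
from sklearn.decomposition import PCA

from .dataset import SpectralDataset

__all__ = [
    "PLSModel",
    "IntervalModel",
    "IPLSResult",
    "pca",
    "pls1_fit",
    "cv_folds",
    "rmsecv",
    "rmsecv_path",
    "split_intervals",
    "ipls_select",
    "IPLSSelector",
]


def pca(data: SpectralDataset | np.ndarray):
    """Mean-centred PCA; returns (scores, explained_variance_fractions)."""
    X = data.intensities if isinstance(data, SpectralDataset) else np.asarray(data)
    if X.shape[0] < 2:
        raise ValueError("PCA needs at least 2 samples")
    model = PCA(svd_solver="full")
    scores = model.fit_transform(X)
    return scores, model.explained_variance_ratio_


@dataclass
class PLSModel:
    """PLS1 model fitted by NIPALS with mean-centring, no variable scaling.

    `coef_path` holds the regression vector for every latent-variable count
    1..n_latent, so cross-validation can score all model orders from one fit.
    Prediction is affine: yhat = (x - x_mean) @ b + y_mean.
    """

    n_latent: int
    x_mean: np.ndarray
    y_mean: float
    weights: np.ndarray      # (p, A) normalised weight vectors
    loadings: np.ndarray     # (p, A) X loadings
    scores: np.ndarray       # (n, A) training scores
    y_loadings: np.ndarray   # (A,)
    coef_path: np.ndarray    # (A, p)

    @property
    def coef_(self) -> np.ndarray:
        return self.coef_path[self.n_latent - 1]

    def predict(self, X: np.ndarray, n_latent: int | None = None) -> np.ndarray:
        a = self.n_latent if n_latent is None else n_latent
        if not 1 <= a <= self.coef_path.shape[0]:
            raise ValueError(f"n_latent must be in 1..{self.coef_path.shape[0]}")
        X = np.asarray(X, dtype=float)
        return (X - self.x_mean) @ self.coef_path[a - 1] + self.y_mean

    def predict_path(self, X: np.ndarray) -> np.ndarray:
        """Predictions for every LV count at once, shape (A, n)."""
        X = np.asarray(X, dtype=float)
        return (X - self.x_mean) @ self.coef_path.T + self.y_mean  # (n, A)


def pls1_fit(X: np.ndarray, y: np.ndarray, n_latent: int) -> PLSModel:
    """NIPALS PLS1.  Deterministic: each component is a closed-form pass
    (single-response PLS needs no inner iteration)."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    if y.shape != (n,):
        raise ValueError("y length must match rows of X")
    max_rank = min(n - 1, p)
    if not 1 <= n_latent <= max_rank:
        raise ValueError(f"n_latent must be in 1..{max_rank} "
                         f"(n={n}, p={p}), got {n_latent}")
    x_mean = X.mean(axis=0)
    y_mean = y.mean()
    E = X - x_mean
    f = y - y_mean
    W = np.zeros((p, n_latent))
    P = np.zeros((p, n_latent))
    T = np.zeros((n, n_latent))
    q = np.zeros(n_latent)
    coef_path = np.zeros((n_latent, p))
    a_done = 0
    for a in range(n_latent):
        w = E.T @ f
        nw = np.linalg.norm(w)
        if nw < 1e-12:        # residual orthogonal to X: nothing left to fit
            break
        w /= nw
        t = E @ w
        tt = t @ t
        if tt < 1e-24:
            break
        pvec = E.T @ t / tt
        q[a] = (f @ t) / tt
        W[:, a], P[:, a], T[:, a] = w, pvec, t
        E = E - np.outer(t, pvec)
        f = f - q[a] * t
        a_done = a + 1
        # regression vector for models with 1..a+1 components
        R = np.linalg.solve(P[:, :a_done].T @ W[:, :a_done],
                            np.eye(a_done))
        coef_path[a] = W[:, :a_done] @ (R @ q[:a_done])
    for a in range(a_done, n_latent):  # degenerate tail: keep last model
        coef_path[a] = coef_path[a - 1] if a > 0 else 0.0
    return PLSModel(n_latent=n_latent, x_mean=x_mean, y_mean=y_mean,
                    weights=W, loadings=P, scores=T, y_loadings=q,
                    coef_path=coef_path)


def cv_folds(n: int, n_folds: int = 10, scheme: str = "contiguous"
             ) -> list[np.ndarray]:
    """Deterministic fold assignment over sample indices 0..n-1.

    'contiguous' = consecutive blocks; 'venetian' = every n_folds-th sample
    (venetian blinds); 'loo' = leave-one-out.
    """
    idx = np.arange(n)
    if scheme == "loo":
        return [np.array([i]) for i in idx]
    if n_folds < 2 or n_folds > n:
        raise ValueError("need 2 <= n_folds <= n")
    if scheme == "contiguous":
        return [f for f in np.array_split(idx, n_folds)]
    if scheme == "venetian":
        return [idx[f::n_folds] for f in range(n_folds)]
    raise ValueError(f"unknown cv scheme {scheme!r}")


def rmsecv_path(X: np.ndarray, y: np.ndarray, max_latent: int,
                folds: list[np.ndarray]) -> np.ndarray:
    """RMSECV for every LV count 1..max_latent (one PLS fit per fold).

    Every sample is predicted exactly once; max_latent is validated against
    the smallest training fold.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n = len(y)
    counts = np.zeros(n, dtype=int)
    resid = np.zeros((max_latent, n))
    for fold in folds:
        train = np.setdiff1d(np.arange(n), fold, assume_unique=True)
        if len(train) - 1 < max_latent:
            raise ValueError(
                f"fold leaves only {len(train)} training samples; "
                f"cannot fit {max_latent} latent variables")
        model = pls1_fit(X[train], y[train], max_latent)
        resid[:, fold] = model.predict_path(X[fold]).T - y[fold]
        counts[fold] += 1
    if np.any(counts != 1):
        raise ValueError("cv folds must predict every sample exactly once")
    return np.sqrt(np.mean(resid**2, axis=1))


def rmsecv(X, y, n_latent: int, folds: list[np.ndarray]) -> float:
    return float(rmsecv_path(X, y, n_latent, folds)[n_latent - 1])


def split_intervals(n_vars: int, k: int) -> list[tuple[int, int]]:
    """k contiguous index ranges (1-based, inclusive) covering 1..n_vars.

    Sizes differ by at most one; the n_vars mod k larger intervals come
    first, e.g. 13,435 variables over k=14 gives nine intervals of 960
    followed by five of 959.
    """
    if not 1 <= k <= n_vars:
        raise ValueError(f"need 1 <= k <= n_vars, got k={k}, n_vars={n_vars}")
    base, rem = divmod(n_vars, k)
    out = []
    start = 1
    for i in range(k):
        size = base + (1 if i < rem else 0)
        out.append((start, start + size - 1))
        start += size
    return out


@dataclass
class IntervalModel:
    """One local PLS model in the iPLS scan."""

    k: int                  # number of subintervals in this subdivision
    interval_index: int     # 1-based position within the subdivision
    var_start: int          # 1-based inclusive variable range
    var_stop: int
    wavelength_lo: float
    wavelength_hi: float
    best_n_latent: int
    rmsecv: float

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class IPLSResult:
    best: IntervalModel
    table: list[IntervalModel]          # every (k, interval) scanned
    global_rmsecv: float
    global_n_latent: int
    cv_scheme: str
    n_folds: int

    def table_for_k(self, k: int) -> list[IntervalModel]:
        return [m for m in self.table if m.k == k]


def _best_lv(path: np.ndarray) -> tuple[int, float]:
    a = int(np.argmin(path))            # ties resolve toward fewer LVs
    return a + 1, float(path[a])


def ipls_select(X: np.ndarray, y: np.ndarray,
                wavelengths: np.ndarray | None = None,
                k_range=range(10, 31), max_latent: int = 15,
                n_folds: int = 10, cv_scheme: str = "contiguous"
                ) -> IPLSResult:
    """Scan every subdivision k in `k_range` and every subinterval; return
    the subinterval whose cross-validated local PLS model is best.

    Intervals narrower than the LV budget get their LV count capped at the
    interval width (and the training-fold rank).  The winner is the lowest
    RMSECV over all (k, interval); ties break toward the first scanned
    (smaller k, then lower interval index).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    if wavelengths is None:
        wavelengths = np.arange(1, p + 1, dtype=float)
    folds = cv_folds(n, n_folds, cv_scheme)
    min_train = min(n - len(f) for f in folds)
    table: list[IntervalModel] = []
    for k in k_range:
        for idx, (lo, hi) in enumerate(split_intervals(p, k), start=1):
            width = hi - lo + 1
            cap = min(max_latent, width, min_train - 1)
            path = rmsecv_path(X[:, lo - 1:hi], y, cap, folds)
            best_lv, best_rmsecv = _best_lv(path)
            table.append(IntervalModel(
                k=k, interval_index=idx, var_start=lo, var_stop=hi,
                wavelength_lo=float(wavelengths[lo - 1]),
                wavelength_hi=float(wavelengths[hi - 1]),
                best_n_latent=best_lv, rmsecv=best_rmsecv))
    best = min(table, key=lambda m: m.rmsecv)
    g_cap = min(max_latent, p, min_train - 1)
    g_path = rmsecv_path(X, y, g_cap, folds)
    g_lv, g_rmsecv = _best_lv(g_path)
    return IPLSResult(best=best, table=table, global_rmsecv=g_rmsecv,
                      global_n_latent=g_lv, cv_scheme=cv_scheme,
                      n_folds=n_folds)


from sklearn.base import BaseEstimator, TransformerMixin  # noqa: E402


class IPLSSelector(BaseEstimator, TransformerMixin):
    """sklearn-style feature selector wrapping `ipls_select`.

    After `fit(X, y)`, `transform(X)` returns only the columns of the
    selected subinterval.  `wavelengths` is optional and only used for
    reporting the selected band in nm.
    """

    def __init__(self, k_min: int = 10, k_max: int = 30, max_latent: int = 15,
                 n_folds: int = 10, cv_scheme: str = "contiguous",
                 wavelengths=None):
        self.k_min = k_min
        self.k_max = k_max
        self.max_latent = max_latent
        self.n_folds = n_folds
        self.cv_scheme = cv_scheme
        self.wavelengths = wavelengths

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        self.result_ = ipls_select(
            X, y, wavelengths=self.wavelengths,
            k_range=range(self.k_min, self.k_max + 1),
            max_latent=self.max_latent, n_folds=self.n_folds,
            cv_scheme=self.cv_scheme)
        best = self.result_.best
        self.support_ = np.zeros(X.shape[1], dtype=bool)
        self.support_[best.var_start - 1:best.var_stop] = True
        return self

    def transform(self, X):
        X = np.asarray(X)
        if X.shape[1] != self.support_.size:
            raise ValueError("feature count differs from fit")
        return X[:, self.support_]
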