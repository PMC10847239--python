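"""NIPALS partial least squares regression with cross-validated latent-variable
choice and the chemometric evaluation metrics (R2, RMSE, RPD).

The regressor autoscales X (column mean/unit variance from the training set)
and centers y, extracts components by NIPALS deflation, and exposes
regression coefficients back-transformed to the original units.  For a
single response the per-component weight update is closed-form, so a full
coefficient path over 1..A components costs one pass — which keeps
cross-validation (and the CARS selector built on top of it) cheap.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

__all__ = [
    "PLSRNipals",
    "fit_plsr",
    "choose_lvs",
    "cv_rmse_path",
    "stratified_folds",
    "evaluate",
    "EvaluationReport",
]

_TOL = 1e-12


def _autoscale_fit(X, scale=True):
    mean = X.mean(axis=0)
    if scale:
        sd = X.std(axis=0, ddof=1)
        zero = np.flatnonzero(sd == 0)
        if zero.size:
            raise ValueError(f"zero-variance column(s) {zero.tolist()[:10]}")
    else:
        sd = np.ones(X.shape[1])
    return mean, sd


def _nipals(Xc: np.ndarray, yc: np.ndarray, max_components: int):
    """NIPALS deflation on preprocessed data.

    Returns (W, P, q, T): x-weights, x-loadings, y-loadings and scores, one
    column/entry per extracted component (may stop early on exhausted
    residual variance).
    """
    X = Xc.copy()
    y = yc.astype(float).copy()
    n, p = X.shape
    A = int(min(max_components, max(n - 1, 1), p))
    W = np.zeros((p, A))
    P = np.zeros((p, A))
    q = np.zeros(A)
    T = np.zeros((n, A))
    a = 0
    for a in range(A):
        w = X.T @ y
        nw = np.linalg.norm(w)
        if nw < _TOL:
            break
        w /= nw
        t = X @ w
        tt = float(t @ t)
        if tt < _TOL:
            break
        p_a = X.T @ t / tt
        q_a = float(y @ t) / tt
        X -= np.outer(t, p_a)
        y -= q_a * t
        W[:, a], P[:, a], q[a], T[:, a] = w, p_a, q_a, t
    else:
        a = A
    return W[:, :a], P[:, :a], q[:a], T[:, :a]


def coefficient_paths(W: np.ndarray, P: np.ndarray, q: np.ndarray) -> np.ndarray:
    """Scaled-space regression coefficients for 1..A components, p x A."""
    A = W.shape[1]
    paths = np.zeros((W.shape[0], A))
    for k in range(1, A + 1):
        Wk, Pk, qk = W[:, :k], P[:, :k], q[:k]
        # P'W is unit upper triangular; solve rather than invert
        paths[:, k - 1] = Wk @ np.linalg.solve(Pk.T @ Wk, qk)
    return paths


class PLSRNipals(RegressorMixin, BaseEstimator):
    """NIPALS PLS regression for a single response.

    Parameters
    ----------
    n_components : int
        Number of latent variables to extract (capped at min(n-1, p)).
    scale : bool
        Autoscale X columns to unit (ddof=1) variance; y is always centered.
    """

    def __init__(self, n_components: int = 2, scale: bool = True):
        self.n_components = n_components
        self.scale = scale

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float).ravel()
        if X.ndim != 2 or X.shape[0] != y.size:
            raise ValueError("X must be 2-D with one row per element of y")
        if self.n_components < 1:
            raise ValueError("n_components must be >= 1")
        if self.n_components > min(X.shape[0] - 1, X.shape[1]):
            raise ValueError(
                f"n_components={self.n_components} exceeds min(n-1, p)="
                f"{min(X.shape[0] - 1, X.shape[1])}"
            )
        if not np.isfinite(X).all():
            raise ValueError("X contains non-finite values")
        self.x_mean_, self.x_std_ = _autoscale_fit(X, self.scale)
        self.y_mean_ = float(y.mean())
        Xc = (X - self.x_mean_) / self.x_std_
        yc = y - self.y_mean_
        W, P, q, T = _nipals(Xc, yc, self.n_components)
        self.x_weights_, self.x_loadings_, self.y_loadings_, self.x_scores_ = W, P, q, T
        self.n_components_ = W.shape[1]
        b_scaled = coefficient_paths(W, P, q)[:, -1] if self.n_components_ else np.zeros(X.shape[1])
        self.coef_ = b_scaled / self.x_std_
        self.intercept_ = self.y_mean_ - float(self.x_mean_ @ self.coef_)
        self.n_features_in_ = X.shape[1]
        return self

    def predict(self, X):
        check_is_fitted(self, "coef_")
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[None, :]
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"X has {X.shape[1]} columns, model was fit with {self.n_features_in_}"
            )
        return X @ self.coef_ + self.intercept_


def fit_plsr(X, y, n_components: int, scale: bool = True) -> PLSRNipals:
    return PLSRNipals(n_components=n_components, scale=scale).fit(X, y)


def stratified_folds(y, n_folds: int, seed: int | None = 0) -> np.ndarray:
    """Contiguous-stratified CV assignment: samples sorted by y are dealt into
    folds chunk by chunk (each chunk of ``n_folds`` neighbors contributes one
    sample per fold, in seeded random order), so every fold spans the full
    response range — avoiding drying-stage leakage between folds."""
    y = np.asarray(y, dtype=float)
    if n_folds < 2 or n_folds > y.size:
        raise ValueError("need 2 <= n_folds <= n_samples")
    order = np.argsort(y, kind="stable")
    rng = np.random.default_rng(seed)
    folds = np.empty(y.size, dtype=int)
    for start in range(0, y.size, n_folds):
        chunk = order[start : start + n_folds]
        labels = rng.permutation(n_folds)[: chunk.size]
        folds[chunk] = labels
    return folds


def cv_rmse_path(X, y, max_lv: int = 10, cv_folds: int = 5, seed: int | None = 0):
    """Cross-validated RMSE for 1..A latent variables (A capped by the
    smallest training split).  Returns a 1-D array of length A."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    folds = stratified_folds(y, cv_folds, seed)
    A = min(max_lv, X.shape[1])
    sq_err = None
    for f in range(cv_folds):
        tr, va = folds != f, folds == f
        mean, sd = _autoscale_fit(X[tr])
        Xc = (X[tr] - mean) / sd
        yc = y[tr] - y[tr].mean()
        W, P, q, _ = _nipals(Xc, yc, min(A, tr.sum() - 1))
        paths = coefficient_paths(W, P, q)  # p x a_fold
        Xv = (X[va] - mean) / sd
        pred = Xv @ paths + y[tr].mean()  # n_val x a_fold
        a_fold = paths.shape[1]
        if sq_err is None:
            sq_err = np.zeros(A)
            counts = np.zeros(A)
        resid2 = (pred - y[va][:, None]) ** 2
        sq_err[:a_fold] += resid2.sum(axis=0)
        # folds that extracted fewer components reuse their last available fit
        if a_fold < A:
            sq_err[a_fold:] += resid2[:, -1].sum()
        counts[:] += va.sum()
    return np.sqrt(sq_err / counts)


def choose_lvs(X, y, max_lv: int = 10, cv_folds: int = 5, seed: int | None = 0) -> int:
    """Latent-variable count minimizing cross-validated RMSE (ties -> fewer)."""
    rmse = cv_rmse_path(X, y, max_lv=max_lv, cv_folds=cv_folds, seed=seed)
    return int(np.argmin(rmse)) + 1


@dataclass
class EvaluationReport:
    """Calibration/validation metrics for one model variant (one report row)."""

    r2c: float
    rmsec: float
    r2v: float
    rmsev: float
    rpd: float
    lvs: int | None = None
    model: str = ""
    recipe: str = ""
    n_variables: int | None = None

    def as_row(self) -> dict:
        return {
            "Model": self.model,
            "Pre-processing": self.recipe,
            "Variables": self.n_variables,
            "LVs": self.lvs,
            "R2c": self.r2c,
            "RMSEC": self.rmsec,
            "R2v": self.r2v,
            "RMSEV": self.rmsev,
            "RPD": self.rpd,
        }


def _r2(y, yhat) -> float:
    y = np.asarray(y, dtype=float)
    ss_tot = float(((y - y.mean()) ** 2).sum())
    if ss_tot == 0:
        raise ValueError("R2 undefined: zero variance in reference values")
    return 1.0 - float(((y - np.asarray(yhat)) ** 2).sum()) / ss_tot


def _rmse(y, yhat) -> float:
    return float(np.sqrt(np.mean((np.asarray(y, float) - np.asarray(yhat, float)) ** 2)))


def evaluate(
    y_cal, yhat_cal, y_val, yhat_val, lvs=None, model="", recipe="", n_variables=None
) -> EvaluationReport:
    """R2 and RMSE per set, plus RPD = sample SD(y_val) / RMSEV.

    A perfect validation fit (RMSEV = 0) reports RPD = +inf.
    """
    y_val = np.asarray(y_val, dtype=float)
    if y_val.size < 2:
        raise ValueError("need at least 2 validation samples")
    rmsev = _rmse(y_val, yhat_val)
    sd = float(y_val.std(ddof=1))
    rpd = np.inf if rmsev == 0 else sd / rmsev
    return EvaluationReport(
        r2c=_r2(y_cal, yhat_cal),
        rmsec=_rmse(y_cal, yhat_cal),
        r2v=_r2(y_val, yhat_val),
        rmsev=rmsev,
        rpd=rpd,
        lvs=lvs,
        model=model,
        recipe=recipe,
        n_variables=n_variables,
    )
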