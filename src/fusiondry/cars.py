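"""Competitive adaptive reweighted sampling (CARS) variable selection.

The canonical Monte Carlo scheme: at each of ``n_runs`` iterations a PLSR
model is fit on a random subset of calibration samples using the currently
retained variables; variables are weighted by their normalized absolute
regression coefficients; an exponentially decreasing function (EDF) fixes
how many survive (all p at run 1, down to 2 at the final run); adaptive
reweighted sampling draws that many without replacement with probability
proportional to weight.  The retained set whose full-calibration
cross-validated RMSE is smallest wins (ties break toward fewer variables).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.feature_selection import SelectorMixin
from sklearn.utils.validation import check_is_fitted

from .pls import PLSRNipals, choose_lvs, cv_rmse_path
from .preprocessing import FeatureBlock

__all__ = ["CARSSelector", "CARSResult", "cars_select", "cars_diagnostics_plot_data"]


def edf_counts(p: int, n_runs: int) -> np.ndarray:
    """Retention schedule ceil(r_i * p) with r_i = a*exp(-k*i): all p variables
    at run 1, exactly 2 at run ``n_runs``."""
    if p < 2:
        raise ValueError("need at least 2 candidate variables")
    if n_runs < 2:
        raise ValueError("n_runs must be >= 2")
    k = np.log(p / 2.0) / (n_runs - 1)
    a = (p / 2.0) ** (1.0 / (n_runs - 1))
    i = np.arange(1, n_runs + 1)
    r = a * np.exp(-k * i)
    counts = np.ceil(r * p - 1e-9).astype(int)  # guard: r_N * p == 2 exactly
    return np.clip(counts, 2, p)


@dataclass
class CARSResult:
    """Outcome of one CARS run: winning subset plus per-run diagnostics."""

    selected: np.ndarray
    retained_counts: np.ndarray
    rmsecv: np.ndarray
    best_run: int
    seed: int | None
    labels: list | None = None

    def __post_init__(self):
        if self.selected.size == 0:
            raise ValueError("CARS produced an empty selection")


class CARSSelector(SelectorMixin, BaseEstimator):
    """CARS as a scikit-learn feature selector.

    Parameters
    ----------
    n_runs : int
        Monte Carlo iterations (length of the EDF schedule).
    cv_folds : int
        Folds for the per-run RMSECV scoring and latent-variable choice.
    mc_fraction : float
        Fraction of calibration samples drawn (without replacement) for the
        per-run coefficient fit.
    max_lv : int
        Ceiling on PLSR latent variables.
    random_state : int or None
        Seed for sampling, ARS draws and CV fold assignment.
    """

    def __init__(
        self,
        n_runs: int = 50,
        cv_folds: int = 5,
        mc_fraction: float = 0.8,
        max_lv: int = 10,
        random_state: int | None = 0,
    ):
        self.n_runs = n_runs
        self.cv_folds = cv_folds
        self.mc_fraction = mc_fraction
        self.max_lv = max_lv
        self.random_state = random_state

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float).ravel()
        n, p = X.shape
        if n < self.cv_folds:
            raise ValueError("need at least cv_folds samples")
        if p < 2:
            raise ValueError("need at least 2 candidate variables")
        if np.allclose(y.std(), 0):
            raise ValueError("degenerate response: zero variance")
        sd = X.std(axis=0, ddof=1)
        if np.any(sd == 0):
            raise ValueError(
                f"zero-variance candidate column(s) {np.flatnonzero(sd == 0).tolist()[:10]}"
            )

        rng = np.random.default_rng(self.random_state)
        counts = edf_counts(p, self.n_runs)
        n_sub = max(self.cv_folds, int(round(self.mc_fraction * n)))

        retained = np.arange(p)
        subsets, rmsecv = [], np.empty(self.n_runs)
        for i in range(self.n_runs):
            sub = rng.choice(n, size=min(n_sub, n), replace=False)
            Xs = X[sub][:, retained]
            lv = min(self.max_lv, len(retained), len(sub) - 1)
            lv = choose_lvs(
                Xs, y[sub], max_lv=lv, cv_folds=self.cv_folds,
                seed=int(rng.integers(2**31 - 1)),
            ) if len(retained) > 1 else 1
            model = PLSRNipals(n_components=lv).fit(Xs, y[sub])
            w = np.abs(model.coef_)
            total = w.sum()
            w = w / total if total > 0 else np.full(w.size, 1.0 / w.size)

            target = min(counts[i], len(retained), int((w > 0).sum()))
            target = max(target, 2) if (w > 0).sum() >= 2 else 1
            # adaptive reweighted sampling: weighted draw without replacement
            keep = rng.choice(len(retained), size=target, replace=False, p=w)
            retained = np.sort(retained[keep])

            rmse_path = cv_rmse_path(
                X[:, retained], y, max_lv=min(self.max_lv, len(retained)),
                cv_folds=self.cv_folds, seed=int(rng.integers(2**31 - 1)),
            )
            rmsecv[i] = rmse_path.min()
            subsets.append(retained.copy())

        sizes = np.array([s.size for s in subsets])
        best = int(np.lexsort((sizes, np.round(rmsecv, 12)))[0])
        self.n_features_in_ = p
        self.retained_counts_ = sizes
        self.rmsecv_ = rmsecv
        self.best_run_ = best
        self.selected_idx_ = subsets[best]
        self.support_ = np.zeros(p, dtype=bool)
        self.support_[self.selected_idx_] = True
        return self

    def _get_support_mask(self):
        check_is_fitted(self, "support_")
        return self.support_

    def result(self, labels=None) -> CARSResult:
        check_is_fitted(self, "support_")
        return CARSResult(
            selected=self.selected_idx_.copy(),
            retained_counts=self.retained_counts_.copy(),
            rmsecv=self.rmsecv_.copy(),
            best_run=self.best_run_,
            seed=self.random_state,
            labels=labels,
        )


def cars_select(
    X,
    y,
    n_runs: int = 50,
    cv_folds: int = 5,
    mc_fraction: float = 0.8,
    max_lv: int = 10,
    seed: int | None = 0,
) -> CARSResult:
    """Functional CARS entry point; accepts a FeatureBlock or a plain matrix."""
    labels = None
    if isinstance(X, FeatureBlock):
        labels, X = X.labels, X.values
    sel = CARSSelector(
        n_runs=n_runs, cv_folds=cv_folds, mc_fraction=mc_fraction,
        max_lv=max_lv, random_state=seed,
    ).fit(X, y)
    return sel.result(
        labels=[labels[i] for i in sel.selected_idx_] if labels else None
    )


def cars_diagnostics_plot_data(result: CARSResult) -> pd.DataFrame:
    """Tidy (run, retained count, RMSECV) table for diagnostics plots."""
    return pd.DataFrame(
        {
            "run": np.arange(1, result.rmsecv.size + 1),
            "retained": result.retained_counts,
            "rmsecv": result.rmsecv,
        }
    )
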