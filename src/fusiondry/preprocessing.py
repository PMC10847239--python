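"""Row-wise spectral preprocessing: SNV, Savitzky-Golay derivatives, and the
named recipe composites used throughout the modeling grid.

All operators are scikit-learn transformers (stateless: they act per row, so
fitting learns nothing and no calibration/validation leakage can arise) with
thin functional wrappers that work on :class:`FeatureBlock`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.signal import savgol_filter
from sklearn.base import BaseEstimator, TransformerMixin

__all__ = [
    "FeatureBlock",
    "SNV",
    "SavGolDerivative",
    "snv",
    "savgol_derivative",
    "apply_recipe",
    "RECIPES",
]

#: Recipe names, read left-to-right as application order:
#: FD/SD = first/second Savitzky-Golay derivative, SNV = standard normal variate.
RECIPES = ("RAW", "SNV", "FD-SNV", "SD-SNV", "SNV-FD", "SNV-SD")

#: Standard block widths: 224 spectral bands, 26 image variables, 10 sensors.
STANDARD_WIDTHS = {"spectra": 224, "image": 26, "enose": 10}


@dataclass
class FeatureBlock:
    """n_samples x n_variables matrix with labels and a block role."""

    values: np.ndarray
    labels: list
    role: str = "spectra"

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D (samples x variables)")
        self.labels = [str(l) for l in self.labels]
        if len(self.labels) != self.values.shape[1]:
            raise ValueError("label count must match variable count")
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("labels must be unique")
        if np.isnan(self.values).any():
            raise ValueError("feature block contains NaN")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_variables(self) -> int:
        return self.values.shape[1]

    def with_values(self, values: np.ndarray) -> "FeatureBlock":
        return FeatureBlock(values, list(self.labels), self.role)

    def select(self, indices) -> "FeatureBlock":
        idx = np.asarray(indices, dtype=int)
        return FeatureBlock(self.values[:, idx], [self.labels[i] for i in idx], self.role)

    def rows(self, indices) -> "FeatureBlock":
        return FeatureBlock(self.values[np.asarray(indices, dtype=int)], list(self.labels), self.role)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, columns=self.labels)


class SNV(TransformerMixin, BaseEstimator):
    """Standard normal variate: each row centered to mean 0 and scaled to
    sample (ddof=1) standard deviation 1, removing per-sample multiplicative
    scatter and additive offset effects."""

    def fit(self, X, y=None):
        self.n_features_in_ = np.asarray(X).shape[1]
        return self

    def transform(self, X):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] < 2:
            raise ValueError("SNV needs 2-D input with at least 2 variables per row")
        sd = X.std(axis=1, ddof=1, keepdims=True)
        zero = np.flatnonzero(sd.ravel() == 0)
        if zero.size:
            raise ValueError(f"SNV undefined for zero-variance row(s) {zero.tolist()}")
        return (X - X.mean(axis=1, keepdims=True)) / sd

    def fit_transform(self, X, y=None, **kw):
        return self.fit(X).transform(X)


class SavGolDerivative(TransformerMixin, BaseEstimator):
    """Row-wise Savitzky-Golay derivative filter (same-length output via
    polynomial-fit edge extension)."""

    def __init__(self, deriv: int = 1, window: int = 11, polyorder: int = 2):
        self.deriv = deriv
        self.window = window
        self.polyorder = polyorder

    def _validate(self, n_vars: int):
        if self.deriv not in (1, 2):
            raise ValueError("deriv must be 1 or 2")
        if self.window % 2 == 0:
            raise ValueError("window must be odd")
        if self.polyorder >= self.window:
            raise ValueError("polyorder must be smaller than window")
        if n_vars < self.window:
            raise ValueError(
                f"window {self.window} exceeds variable count {n_vars}"
            )

    def fit(self, X, y=None):
        self.n_features_in_ = np.asarray(X).shape[1]
        self._validate(self.n_features_in_)
        return self

    def transform(self, X):
        X = np.asarray(X, dtype=float)
        self._validate(X.shape[1])
        return savgol_filter(
            X, self.window, self.polyorder, deriv=self.deriv, axis=1, mode="interp"
        )

    def fit_transform(self, X, y=None, **kw):
        return self.fit(X).transform(X)


def snv(block: FeatureBlock) -> FeatureBlock:
    return block.with_values(SNV().fit_transform(block.values))


def savgol_derivative(
    block: FeatureBlock, deriv: int = 1, window: int = 11, polyorder: int = 2
) -> FeatureBlock:
    tr = SavGolDerivative(deriv=deriv, window=window, polyorder=polyorder)
    return block.with_values(tr.fit_transform(block.values))


def _default_window(n_variables: int, window: int | None) -> int:
    if window is not None:
        return window
    # narrow blocks (e.g. the 10-sensor array) cannot host an 11-point window
    return 11 if n_variables >= 11 else 5


def apply_recipe(
    block: FeatureBlock, name: str, window: int | None = None, polyorder: int = 2
) -> FeatureBlock:
    """Apply a named preprocessing recipe; hyphenated names compose left to
    right (``"FD-SNV"`` = first derivative, then SNV)."""
    if name not in RECIPES:
        raise ValueError(f"unknown recipe {name!r}; expected one of {RECIPES}")
    if name == "RAW":
        return block.with_values(block.values.copy())
    out = block
    win = _default_window(block.n_variables, window)
    for step in name.split("-"):
        if step == "SNV":
            out = snv(out)
        elif step in ("FD", "SD"):
            out = savgol_derivative(
                out, deriv=1 if step == "FD" else 2, window=win, polyorder=polyorder
            )
        else:  # pragma: no cover - guarded by RECIPES membership
            raise ValueError(f"unknown recipe step {step!r}")
    return out
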