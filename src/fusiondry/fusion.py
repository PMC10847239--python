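"""Fusion strategies and the end-to-end experiment runner.

Three fusion levels combine the spectral (224-band mean ROI spectrum), image
(26 color/texture variables) and e-nose (10 sensors) blocks:

* pixel level — preprocessed blocks concatenated column-wise;
* feature level — CARS-selected columns of each block concatenated;
* decision level — per-block PLSR predictions combined by multiple linear
  regression, y = b + k1*x_spectra + k2*x_image + k3*x_enose, with weights
  fit on calibration predictions only.

The runner reproduces the full comparison grid: preprocessing-recipe
screening per block, CARS feature models per block, and HSI-only vs
HSI+E-nose fusion at all three levels, under one calibration/validation
split so every variant is comparable.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.cluster import AgglomerativeClustering
from sklearn.decomposition import PCA
from sklearn.utils.validation import check_is_fitted

from . import image_features
from .calibration import mean_spectrum, reflectance_correct, segment_roi
from .cars import cars_select
from .datasets import (
    CubeSpec,
    DryingCurveParams,
    DryingDataset,
    DryingDesign,
    EnoseSpec,
    generate_dataset,
)
from .pls import EvaluationReport, PLSRNipals, choose_lvs, evaluate
from .preprocessing import FeatureBlock, apply_recipe, RECIPES

__all__ = [
    "split_calibration_validation",
    "pixel_fusion",
    "feature_fusion",
    "FusionWeights",
    "DecisionFusion",
    "decision_fusion_fit",
    "decision_fusion_apply",
    "enose_explore",
    "EnoseExploration",
    "extract_feature_blocks",
    "ExperimentConfig",
    "ExperimentReport",
    "run_full_experiment",
]


def split_calibration_validation(
    mc_values, ratio=(3, 1), method: str = "systematic", seed: int | None = None
):
    """Split samples into calibration/validation sets at ``ratio``.

    ``method="systematic"`` ranks samples by reference MC and sends one
    sample per rank period to validation (period = cal + val parts, offset
    chosen mid-period so the validation range is bracketed by calibration
    samples).  ``method="random"`` draws the validation set uniformly with
    ``seed``.  Returns ``(cal_idx, val_idx)`` index arrays.
    """
    mc = np.asarray(mc_values, dtype=float).ravel()
    n = mc.size
    if n < 8:
        raise ValueError("need at least 8 samples to split")
    period = int(ratio[0]) + int(ratio[1])
    if method == "systematic":
        order = np.argsort(mc, kind="stable")
        ranks = np.empty(n, dtype=int)
        ranks[order] = np.arange(n)
        offset = period // 2
        val_mask = (ranks % period) == offset
        # guard: never let the extreme-rank samples leave calibration
        val_mask[order[0]] = False
        val_mask[order[-1]] = False
    elif method == "random":
        rng = np.random.default_rng(seed)
        n_val = n // period * int(ratio[1])
        val_mask = np.zeros(n, dtype=bool)
        val_mask[rng.choice(n, size=n_val, replace=False)] = True
    else:
        raise ValueError(f"unknown split method {method!r}")
    idx = np.arange(n)
    return idx[~val_mask], idx[val_mask]


def pixel_fusion(blocks) -> FeatureBlock:
    """Column-wise concatenation of preprocessed blocks (same sample order)."""
    blocks = list(blocks)
    if not blocks:
        raise ValueError("no blocks to fuse")
    n = blocks[0].n_samples
    if any(b.n_samples != n for b in blocks):
        raise ValueError("all blocks must have the same sample count and order")
    values = np.hstack([b.values for b in blocks])
    labels = [f"{b.role}:{l}" for b in blocks for l in b.labels]
    return FeatureBlock(values, labels, role="fused")


def feature_fusion(selected_blocks) -> FeatureBlock:
    """Concatenate CARS-selected columns of each block, provenance-labeled."""
    blocks = list(selected_blocks)
    for b in blocks:
        if b.n_variables == 0:
            raise ValueError(f"block {b.role!r} has an empty selection")
    return pixel_fusion(blocks)


@dataclass
class FusionWeights:
    """Decision-fusion regression: intercept b and one weight per block."""

    b: float
    k: tuple
    block_names: tuple = ("spectra", "image", "enose")

    @property
    def k1(self):
        return self.k[0]

    @property
    def k2(self):
        return self.k[1]

    @property
    def k3(self):
        return self.k[2] if len(self.k) > 2 else None


class DecisionFusion(RegressorMixin, BaseEstimator):
    """Multiple linear regression over per-block model predictions.

    Fit on calibration predictions only.  Near-collinear predictors (e.g.
    two blocks predicting identically) trigger a small ridge penalty
    fallback with a warning; the ridge solution is the minimum-norm one.
    """

    def __init__(self, ridge: float = 1e-8, cond_threshold: float = 1e10):
        self.ridge = ridge
        self.cond_threshold = cond_threshold

    def fit(self, P, y):
        P = np.asarray(P, dtype=float)
        y = np.asarray(y, dtype=float).ravel()
        if P.ndim != 2 or P.shape[0] != y.size:
            raise ValueError("P must be n_samples x n_blocks, matching y")
        if P.shape[0] < 5:
            raise ValueError("need at least 5 calibration samples")
        A = np.hstack([np.ones((P.shape[0], 1)), P])
        G = A.T @ A
        if np.linalg.cond(G) > self.cond_threshold:
            warnings.warn(
                "collinear block predictions: falling back to ridge "
                f"(penalty {self.ridge:g})",
                RuntimeWarning,
                stacklevel=2,
            )
            G = G + self.ridge * np.eye(G.shape[0])
        beta = np.linalg.solve(G, A.T @ y)
        self.intercept_ = float(beta[0])
        self.coef_ = beta[1:]
        self.n_features_in_ = P.shape[1]
        return self

    def predict(self, P):
        check_is_fitted(self, "coef_")
        P = np.asarray(P, dtype=float)
        if P.ndim != 2 or P.shape[1] != self.n_features_in_:
            raise ValueError("prediction matrix has wrong number of blocks")
        return self.intercept_ + P @ self.coef_

    def weights(self, block_names=("spectra", "image", "enose")) -> FusionWeights:
        check_is_fitted(self, "coef_")
        return FusionWeights(
            b=self.intercept_,
            k=tuple(self.coef_),
            block_names=tuple(block_names[: self.coef_.size]),
        )


def decision_fusion_fit(y_cal, preds_cal: dict, ridge: float = 1e-8) -> FusionWeights:
    """Fit fusion weights by OLS of y_cal on the per-block calibration
    predictions (given as a role -> vector mapping)."""
    names = tuple(preds_cal)
    P = np.column_stack([np.asarray(preds_cal[k], float) for k in names])
    return DecisionFusion(ridge=ridge).fit(P, y_cal).weights(names)


def decision_fusion_apply(weights: FusionWeights, preds_val: dict) -> np.ndarray:
    """Apply fitted fusion weights to per-block validation predictions."""
    if set(preds_val) != set(weights.block_names):
        raise ValueError("prediction blocks do not match fitted weights")
    P = np.column_stack(
        [np.asarray(preds_val[k], float) for k in weights.block_names]
    )
    if len({p.size for p in (np.asarray(preds_val[k]) for k in preds_val)}) > 1:
        raise ValueError("prediction vectors differ in length")
    return weights.b + P @ np.asarray(weights.k)


@dataclass
class EnoseExploration:
    scores: np.ndarray
    explained_variance_ratio: np.ndarray
    cluster_labels: np.ndarray


def enose_explore(block, n_clusters: int = 7) -> EnoseExploration:
    """Unsupervised structure of the sensor array: PCA scores and explained
    variance on the autoscaled 10-sensor block, plus Ward/Euclidean
    agglomerative cluster labels cut at ``n_clusters``."""
    X = block.values if isinstance(block, FeatureBlock) else np.asarray(block, float)
    if X.shape[0] < n_clusters:
        raise ValueError("need at least n_clusters samples")
    sd = X.std(axis=0, ddof=1)
    if np.all(sd == 0):
        raise ValueError("degenerate block: all sensors constant")
    Z = (X - X.mean(axis=0)) / np.where(sd == 0, 1.0, sd)
    pca = PCA(n_components=min(Z.shape[0] - 1, Z.shape[1]), svd_solver="full")
    scores = pca.fit_transform(Z)
    if n_clusters == 1:
        labels = np.zeros(X.shape[0], dtype=int)
    else:
        labels = AgglomerativeClustering(
            n_clusters=n_clusters, linkage="ward", metric="euclidean"
        ).fit_predict(Z)
    return EnoseExploration(scores, pca.explained_variance_ratio_, labels)


def extract_feature_blocks(dataset: DryingDataset):
    """Run calibration -> ROI -> spectra/image features over every sample.

    Returns ``{"spectra": FeatureBlock, "image": FeatureBlock,
    "enose": FeatureBlock}``; cubes are materialized one at a time.
    """
    wl = dataset.cube_spec.wavelengths()
    spectra, images = [], []
    for i in range(len(dataset)):
        raw, white, black, _ = dataset.cube(i)
        cube = reflectance_correct(raw, white, black, wavelengths=wl)
        mask = segment_roi(cube)
        spectra.append(mean_spectrum(cube, mask))
        vec, labels = image_features.image_feature_vector(cube, mask)
        images.append(vec)
    return {
        "spectra": FeatureBlock(
            np.array(spectra), [f"{w:.2f}nm" for w in wl], role="spectra"
        ),
        "image": FeatureBlock(np.array(images), labels, role="image"),
        "enose": FeatureBlock(
            dataset.enose_matrix(), [f"S{k}" for k in range(1, 11)], role="enose"
        ),
    }


@dataclass
class ExperimentConfig:
    """Everything the runner needs; defaults mirror the study design."""

    design: DryingDesign = field(default_factory=DryingDesign)
    curve: DryingCurveParams = field(default_factory=DryingCurveParams)
    cube_spec: CubeSpec = field(default_factory=CubeSpec)
    enose_spec: EnoseSpec = field(default_factory=EnoseSpec)
    seed: int = 0
    recipes: tuple = RECIPES
    # block -> recipe used for CARS selection and all fusion models
    model_recipes: dict = field(
        default_factory=lambda: {"spectra": "FD-SNV", "image": "FD-SNV", "enose": "SNV"}
    )
    split_ratio: tuple = (3, 1)
    split_method: str = "systematic"
    cars_runs: int = 50
    cv_folds: int = 5
    mc_fraction: float = 0.8
    max_lv: int = 10
    run_recipe_screen: bool = True


@dataclass
class ExperimentReport:
    """All evaluation rows plus the manifest of seeds and hyperparameters."""

    rows: list
    manifest: dict
    cars_results: dict = field(default_factory=dict)
    fusion_weights: dict = field(default_factory=dict)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame([r.as_row() for r in self.rows])

    def row(self, model: str, recipe: str | None = None) -> EvaluationReport:
        hits = [
            r
            for r in self.rows
            if r.model == model and (recipe is None or r.recipe == recipe)
        ]
        if len(hits) != 1:
            raise KeyError(f"expected exactly one row for {model!r}/{recipe!r}, got {len(hits)}")
        return hits[0]

    def write(self, out_dir) -> Path:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.to_dataframe().to_csv(out / "report.csv", index=False)
        with open(out / "manifest.yaml", "w") as fh:
            yaml.safe_dump(self.manifest, fh, sort_keys=False)
        for role, res in self.cars_results.items():
            pd.DataFrame(
                {"index": res.selected, "label": res.labels or res.selected}
            ).to_csv(out / f"cars_{role}.csv", index=False)
        return out


def _fit_eval(X_cal, y_cal, X_val, y_val, cfg, seed, model, recipe, n_vars):
    """Choose LVs on calibration, fit, evaluate on both sets."""
    lv_cap = min(cfg.max_lv, X_cal.shape[1], X_cal.shape[0] - 1)
    lvs = choose_lvs(X_cal, y_cal, max_lv=lv_cap, cv_folds=cfg.cv_folds, seed=seed)
    m = PLSRNipals(n_components=lvs).fit(X_cal, y_cal)
    rep = evaluate(
        y_cal, m.predict(X_cal), y_val, m.predict(X_val),
        lvs=lvs, model=model, recipe=recipe, n_variables=n_vars,
    )
    return m, rep


def run_full_experiment(
    config: ExperimentConfig | None = None,
    dataset: DryingDataset | None = None,
    blocks: dict | None = None,
    out_dir=None,
) -> ExperimentReport:
    """Execute the full comparison grid on one dataset and one split.

    ``dataset`` (or a pre-extracted ``blocks`` dict plus ``dataset`` for the
    reference MC) defaults to a fresh synthetic experiment at
    ``config.seed``.  No validation sample influences any fitted parameter:
    CARS, latent-variable choice, PLSR scaling and fusion weights all see
    calibration rows only (row-wise preprocessing carries no cross-sample
    state).
    """
    cfg = config or ExperimentConfig()
    if dataset is None:
        dataset = generate_dataset(
            cfg.design, cfg.curve, cfg.cube_spec, cfg.enose_spec, seed=cfg.seed
        )
    if blocks is None:
        blocks = extract_feature_blocks(dataset)
    y = dataset.mc
    cal, val = split_calibration_validation(
        y, ratio=cfg.split_ratio, method=cfg.split_method, seed=cfg.seed
    )
    y_cal, y_val = y[cal], y[val]
    ss = np.random.SeedSequence(cfg.seed)
    next_seed = lambda: int(ss.spawn(1)[0].generate_state(1)[0] % (2**31 - 1))

    rows, cars_results, weights = [], {}, {}
    block_names = {"spectra": "Spectra", "image": "Image", "enose": "E-nose"}

    # 1. preprocessing-recipe screening on full raw-variable blocks
    if cfg.run_recipe_screen:
        for role, block in blocks.items():
            for recipe in cfg.recipes:
                pre = apply_recipe(block, recipe)
                _, rep = _fit_eval(
                    pre.values[cal], y_cal, pre.values[val], y_val, cfg, next_seed(),
                    model=f"{block_names[role]} RAW", recipe=recipe,
                    n_vars=pre.n_variables,
                )
                rows.append(rep)

    # 2. CARS per block (on its assigned recipe, calibration rows only)
    pre_blocks, sel_blocks, block_preds_cal, block_preds_val = {}, {}, {}, {}
    for role, block in blocks.items():
        recipe = cfg.model_recipes[role]
        pre = apply_recipe(block, recipe)
        pre_blocks[role] = pre
        res = cars_select(
            pre.rows(cal), y_cal,
            n_runs=cfg.cars_runs, cv_folds=cfg.cv_folds,
            mc_fraction=cfg.mc_fraction, max_lv=cfg.max_lv, seed=next_seed(),
        )
        cars_results[role] = res
        sel = pre.select(res.selected)
        sel_blocks[role] = sel
        m, rep = _fit_eval(
            sel.values[cal], y_cal, sel.values[val], y_val, cfg, next_seed(),
            model=f"{block_names[role]} CARS", recipe=recipe,
            n_vars=sel.n_variables,
        )
        rows.append(rep)
        block_preds_cal[role] = m.predict(sel.values[cal])
        block_preds_val[role] = m.predict(sel.values[val])

    # 3. fusion variants: HSI-only (spectra+image) and HSI + E-nose
    for tag, roles in (("HSI", ("spectra", "image")), ("HSI+E-nose", ("spectra", "image", "enose"))):
        pixel = pixel_fusion([pre_blocks[r] for r in roles])
        _, rep = _fit_eval(
            pixel.values[cal], y_cal, pixel.values[val], y_val, cfg, next_seed(),
            model=f"{tag} Pixel", recipe="per-block", n_vars=pixel.n_variables,
        )
        rows.append(rep)

        feat = feature_fusion([sel_blocks[r] for r in roles])
        _, rep = _fit_eval(
            feat.values[cal], y_cal, feat.values[val], y_val, cfg, next_seed(),
            model=f"{tag} Feature", recipe="per-block", n_vars=feat.n_variables,
        )
        rows.append(rep)

        fuser = DecisionFusion().fit(
            np.column_stack([block_preds_cal[r] for r in roles]), y_cal
        )
        yhat_cal = fuser.predict(np.column_stack([block_preds_cal[r] for r in roles]))
        yhat_val = fuser.predict(np.column_stack([block_preds_val[r] for r in roles]))
        weights[tag] = fuser.weights(roles)
        rows.append(
            evaluate(
                y_cal, yhat_cal, y_val, yhat_val,
                lvs=None, model=f"{tag} Decision", recipe="per-block",
                n_variables=len(roles),
            )
        )

    manifest = {
        "seed": int(cfg.seed),
        "split": {
            "method": cfg.split_method,
            "ratio": list(cfg.split_ratio),
            "n_calibration": int(cal.size),
            "n_validation": int(val.size),
        },
        "model_recipes": dict(cfg.model_recipes),
        "cars": {
            "n_runs": cfg.cars_runs,
            "cv_folds": cfg.cv_folds,
            "mc_fraction": cfg.mc_fraction,
            "max_lv": cfg.max_lv,
        },
        "dataset": dataset.manifest(),
    }
    report = ExperimentReport(rows, manifest, cars_results, weights)
    if out_dir is not None:
        report.write(out_dir)
    return report
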