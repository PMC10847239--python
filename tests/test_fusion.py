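"""Calibration/validation splitting, the three fusion levels, e-nose
exploration and the end-to-end experiment runner."""

import dataclasses

import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score

from fusiondry.datasets import (
    CubeSpec,
    DryingCurveParams,
    DryingDesign,
    generate_dataset,
    mc_curve,
)
from fusiondry.fusion import (
    DecisionFusion,
    ExperimentConfig,
    decision_fusion_apply,
    decision_fusion_fit,
    enose_explore,
    feature_fusion,
    pixel_fusion,
    run_full_experiment,
    split_calibration_validation,
)
from fusiondry.preprocessing import FeatureBlock


def _blocks(n=12, widths=(224, 26, 10), seed=0):
    rng = np.random.default_rng(seed)
    roles = ("spectra", "image", "enose")
    return [
        FeatureBlock(rng.standard_normal((n, w)), [f"x{i}" for i in range(w)], role)
        for w, role in zip(widths, roles)
    ]


class TestSplit:
    def test_systematic_split_counts_104(self):
        mc = np.random.default_rng(0).uniform(0.15, 0.73, 104)
        cal, val = split_calibration_validation(mc)
        assert cal.size == 78 and val.size == 26

    def test_disjoint_and_covering(self):
        mc = np.random.default_rng(1).uniform(0, 1, 40)
        cal, val = split_calibration_validation(mc)
        assert np.array_equal(np.sort(np.concatenate([cal, val])), np.arange(40))

    def test_validation_range_bracketed_by_calibration(self):
        mc = np.random.default_rng(2).uniform(0, 1, 104)
        cal, val = split_calibration_validation(mc)
        assert mc[cal].min() < mc[val].min() and mc[val].max() < mc[cal].max()

    def test_random_method_seeded(self):
        mc = np.random.default_rng(3).uniform(0, 1, 40)
        a = split_calibration_validation(mc, method="random", seed=7)
        b = split_calibration_validation(mc, method="random", seed=7)
        assert np.array_equal(a[1], b[1])

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            split_calibration_validation(np.arange(5.0))


class TestConcatenationFusion:
    def test_pixel_fusion_widths(self):
        fused = pixel_fusion(_blocks())
        assert fused.n_variables == 224 + 26 + 10
        hsi = pixel_fusion(_blocks(widths=(224, 26))[:2])
        assert hsi.n_variables == 250

    def test_labels_prefixed_and_unique(self):
        fused = pixel_fusion(_blocks())
        assert fused.labels[0] == "spectra:x0" and fused.labels[-1] == "enose:x9"
        assert len(set(fused.labels)) == fused.n_variables

    def test_sample_order_preserved(self):
        blocks = _blocks()
        fused = pixel_fusion(blocks)
        assert np.array_equal(fused.values[:, :224], blocks[0].values)

    def test_row_count_mismatch_rejected(self):
        a, b, _ = _blocks()
        with pytest.raises(ValueError):
            pixel_fusion([a, b.rows(range(5))])

    def test_feature_fusion_sizes_and_empty_selection(self):
        blocks = _blocks()
        sel = [blocks[0].select(range(14)), blocks[1].select(range(16)), blocks[2].select(range(8))]
        fused = feature_fusion(sel)
        assert fused.n_variables == 38
        with pytest.raises(ValueError, match="empty"):
            feature_fusion([blocks[0].select([])])

    def test_permuting_samples_permutes_fusion(self):
        blocks = _blocks()
        perm = np.random.default_rng(4).permutation(12)
        fused = pixel_fusion(blocks)
        fused_perm = pixel_fusion([b.rows(perm) for b in blocks])
        assert np.array_equal(fused.values[perm], fused_perm.values)


class TestDecisionFusion:
    def test_perfect_spectral_predictor_oracle(self):
        # OLS oracle: if one predictor equals y, fused calibration residual is 0
        rng = np.random.default_rng(5)
        y = rng.uniform(0, 1, 30)
        preds = {
            "spectra": y.copy(),
            "image": rng.uniform(0, 1, 30),
            "enose": rng.uniform(0, 1, 30),
        }
        w = decision_fusion_fit(y, preds)
        fused = decision_fusion_apply(w, preds)
        assert np.allclose(fused, y, atol=1e-8)
        # matches the normal-equations solution
        A = np.hstack([np.ones((30, 1))] + [preds[k][:, None] for k in preds])
        beta, *_ = np.linalg.lstsq(A, y, rcond=None)
        assert np.allclose([w.b, *w.k], beta, atol=1e-6)

    def test_exact_collinearity_ridge_fallback(self):
        y = np.linspace(0.1, 0.9, 20)
        preds = {"spectra": y, "image": y, "enose": y}
        with pytest.warns(RuntimeWarning, match="collinear"):
            w = decision_fusion_fit(y, preds)
        fused = decision_fusion_apply(w, preds)
        assert np.allclose(fused, y, atol=1e-4)
        assert abs(w.b) < 1e-3 and sum(w.k) == pytest.approx(1.0, abs=1e-4)

    def test_weight_shape_and_identity_weights(self):
        from fusiondry.fusion import FusionWeights

        y = np.random.default_rng(6).uniform(0, 1, 10)
        w = FusionWeights(b=0.0, k=(1.0, 0.0, 0.0))
        preds = {"spectra": y, "image": np.zeros(10), "enose": np.zeros(10)}
        assert np.allclose(decision_fusion_apply(w, preds), y)
        const = FusionWeights(b=0.25, k=(0.0, 0.0, 0.0))
        assert np.allclose(decision_fusion_apply(const, preds), 0.25)
        assert w.k1 == 1.0 and w.k2 == 0.0 and w.k3 == 0.0

    def test_in_sample_r2_never_below_components(self):
        # OLS over component predictions cannot do worse in-sample
        rng = np.random.default_rng(7)
        y = rng.uniform(0, 1, 50)
        preds = {k: y + s * rng.standard_normal(50) for k, s in
                 [("spectra", 0.03), ("image", 0.1), ("enose", 0.06)]}
        w = decision_fusion_fit(y, preds)
        fused = decision_fusion_apply(w, preds)
        sse_fused = ((fused - y) ** 2).sum()
        for p in preds.values():
            assert sse_fused <= ((p - y) ** 2).sum() + 1e-9

    def test_length_mismatch_rejected(self):
        from fusiondry.fusion import FusionWeights

        w = FusionWeights(b=0.0, k=(1.0, 0.0))
        with pytest.raises(ValueError):
            decision_fusion_apply(w, {"spectra": np.zeros(3)})


class TestEnoseExplore:
    def test_noise_off_stages_recovered_exactly(self):
        # 13 distinct noise-free stage centroids: a 13-cut reproduces stages
        ds = generate_dataset(
            cube_spec=CubeSpec(height=8, width=8, n_bands=16), seed=0, noise=False
        )
        res = enose_explore(ds.enose_matrix(), n_clusters=13)
        assert adjusted_rand_score(ds.stage_times, res.cluster_labels) == 1.0

    def test_seven_separated_groups_recovered(self):
        ds = generate_dataset(
            DryingDesign(stage_times=(0, 2, 4, 6, 8, 10, 12)),
            cube_spec=CubeSpec(height=8, width=8, n_bands=16),
            seed=1, noise=False,
        )
        res = enose_explore(ds.enose_matrix(), n_clusters=7)
        assert adjusted_rand_score(ds.stage_times, res.cluster_labels) == 1.0

    def test_variance_ratios_and_single_cluster(self):
        rng = np.random.default_rng(8)
        X = rng.standard_normal((20, 10))
        res = enose_explore(X, n_clusters=1)
        assert np.all(np.diff(res.explained_variance_ratio) <= 1e-12)
        assert res.explained_variance_ratio.sum() <= 1 + 1e-9
        assert np.all(res.cluster_labels == 0)

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            enose_explore(np.ones((3, 10)) + np.arange(3)[:, None], n_clusters=7)


@pytest.fixture(scope="module")
def small_report(small_dataset, small_blocks):
    cfg = ExperimentConfig(
        design=small_dataset.design,
        cube_spec=small_dataset.cube_spec,
        seed=42,
        cars_runs=25,
        run_recipe_screen=False,
    )
    return run_full_experiment(cfg, dataset=small_dataset, blocks=small_blocks)


class TestRunner:
    def test_report_has_every_variant_once(self, small_report):
        df = small_report.to_dataframe()
        expected = {
            "Spectra CARS", "Image CARS", "E-nose CARS",
            "HSI Pixel", "HSI Feature", "HSI Decision",
            "HSI+E-nose Pixel", "HSI+E-nose Feature", "HSI+E-nose Decision",
        }
        assert set(df["Model"]) == expected
        assert not df["Model"].duplicated().any()

    def test_rerun_same_seed_identical(self, small_dataset, small_blocks, small_report):
        cfg = ExperimentConfig(
            design=small_dataset.design,
            cube_spec=small_dataset.cube_spec,
            seed=42,
            cars_runs=25,
            run_recipe_screen=False,
        )
        again = run_full_experiment(cfg, dataset=small_dataset, blocks=small_blocks)
        a, b = small_report.to_dataframe(), again.to_dataframe()
        assert a.equals(b)

    def test_report_roundtrip(self, small_report, tmp_path):
        out = small_report.write(tmp_path / "exp")
        assert (out / "report.csv").exists()
        assert (out / "manifest.yaml").exists()
        assert (out / "cars_spectra.csv").exists()

    def test_leakage_audit_validation_rows_inert(self, small_dataset, small_blocks, small_report):
        # perturbing validation-row features changes no fitted parameter
        y = small_dataset.mc
        cal, val = split_calibration_validation(y)
        rng = np.random.default_rng(99)
        perturbed = {}
        for role, block in small_blocks.items():
            vals = block.values.copy()
            vals[val] += rng.uniform(0.5, 1.5, (val.size, block.n_variables))
            perturbed[role] = FeatureBlock(vals, list(block.labels), block.role)
        cfg = ExperimentConfig(
            design=small_dataset.design,
            cube_spec=small_dataset.cube_spec,
            seed=42,
            cars_runs=25,
            run_recipe_screen=False,
        )
        rep_p = run_full_experiment(cfg, dataset=small_dataset, blocks=perturbed)
        for role in ("spectra", "image", "enose"):
            assert np.array_equal(
                small_report.cars_results[role].selected, rep_p.cars_results[role].selected
            )
        for tag in ("HSI", "HSI+E-nose"):
            assert small_report.fusion_weights[tag].b == rep_p.fusion_weights[tag].b
            assert small_report.fusion_weights[tag].k == rep_p.fusion_weights[tag].k
        a = small_report.to_dataframe().set_index("Model")
        b = rep_p.to_dataframe().set_index("Model")
        # calibration-side metrics and LV choices are untouched
        assert a["LVs"].equals(b["LVs"])
        assert np.allclose(a["R2c"], b["R2c"]) and np.allclose(a["RMSEC"], b["RMSEC"])
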