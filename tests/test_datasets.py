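"""Synthetic drying-experiment generator: curve anchors, determinism,
closed-form checks and the oven-drying moisture formula."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import spearmanr

from fusiondry.datasets import (
    CubeSpec,
    DryingCurveParams,
    DryingDesign,
    EnoseSpec,
    compute_mc,
    default_wavelengths,
    enose_response,
    foreground_spectrum,
    generate_cube,
    generate_dataset,
    generate_enose,
    mc_curve,
)


class TestMcCurve:
    def test_curve_anchors_boiled_and_final(self):
        # the default parameterization pins the boiled and 12 h stages
        assert mc_curve(0.0) == pytest.approx(0.7275, abs=1e-12)
        assert mc_curve(12.0) == pytest.approx(0.1567, abs=1e-12)

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(
        t1=st.floats(0.0, 12.0, allow_nan=False),
        t2=st.floats(0.0, 12.0, allow_nan=False),
    )
    def test_monotone_nonincreasing(self, t1, t2):
        lo, hi = sorted((t1, t2))
        assert mc_curve(lo) >= mc_curve(hi)

    def test_rate_peaks_mid_drying(self):
        # the numerical drying rate is maximal between 3 and 5 h
        t = np.linspace(0, 12, 1201)
        rate = -np.gradient(mc_curve(t), t)
        assert 3.0 <= t[np.argmax(rate)] <= 5.0

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError):
            mc_curve(-0.5)

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            DryingCurveParams(mc_start=0.2, mc_end=0.7)


class TestDesign:
    def test_default_design_yields_104_samples(self):
        assert DryingDesign().n_samples == 104

    @pytest.mark.parametrize(
        "stages,reps,expected", [((0, 1), 1, 2), ((0, 2, 4), 3, 9)]
    )
    def test_count_arithmetic(self, stages, reps, expected):
        ds = generate_dataset(
            DryingDesign(stage_times=stages, replicates_per_stage=reps), seed=1
        )
        assert len(ds) == expected

    def test_nonincreasing_stage_times_rejected(self):
        with pytest.raises(ValueError):
            DryingDesign(stage_times=(0, 2, 1))


class TestDatasetGeneration:
    def test_seeded_generation_is_bit_identical(self):
        a = generate_dataset(seed=7)
        b = generate_dataset(seed=7)
        assert np.array_equal(a.mc, b.mc)
        assert np.array_equal(a.enose_matrix(), b.enose_matrix())
        ra, *_ = a.cube(13)
        rb, *_ = b.cube(13)
        assert np.array_equal(ra, rb)

    def test_mc_monotone_in_expectation(self):
        ds = generate_dataset(seed=0)
        stage_means = [
            ds.mc[ds.stage_times == t].mean() for t in ds.design.stage_times
        ]
        assert np.all(np.diff(stage_means) < 0)

    def test_replicate_sd_matches_configuration(self):
        # >=1000 replicates at one stage: recovered SD within 3 standard errors
        sd = 0.012
        ds = generate_dataset(
            DryingDesign(stage_times=(0, 6), replicates_per_stage=600),
            DryingCurveParams(replicate_sd=sd),
            cube_spec=CubeSpec(height=4, width=4),
            seed=11,
        )
        resid = ds.mc - np.where(ds.stage_times == 0, mc_curve(0.0), mc_curve(6.0))
        n = resid.size
        se = sd / np.sqrt(2 * (n - 1))
        assert abs(resid.std(ddof=1) - sd) < 3 * se


class TestCube:
    def test_noise_off_foreground_equals_closed_form(self, noise_off_cube):
        spec = noise_off_cube["spec"]
        wl = spec.wavelengths()
        refl = (noise_off_cube["raw"].astype(float) - noise_off_cube["black"]) / (
            noise_off_cube["white"] - noise_off_cube["black"]
        )
        fg = refl[noise_off_cube["mask"]]
        # independent evaluation of the generator's analytic spectrum model
        baseline = spec.base_low + (spec.base_high - spec.base_low) / (
            1 + np.exp(-(wl - spec.base_center_nm) / spec.base_scale_nm)
        )
        w_vis = 1 / (1 + np.exp((wl - spec.vis_edge_nm) / spec.vis_width_nm))
        depth = spec.depth_offset + spec.depth_slope * noise_off_cube["mc"]
        bands = sum(
            a * np.exp(-0.5 * ((wl - c) / s) ** 2)
            for c, s, a in zip(spec.band_centers_nm, spec.band_sigmas_nm, spec.band_amps)
        )
        expected = baseline * (
            1 - spec.darkening * (1 - noise_off_cube["mc"]) * w_vis
        ) - depth * bands
        assert np.allclose(fg, expected[None, :], atol=1e-6)

    def test_absorption_depth_increases_with_moisture(self, small_cube_spec):
        wl = small_cube_spec.wavelengths()
        i960 = int(np.argmin(np.abs(wl - 960)))
        wet = foreground_spectrum(0.70, wl, small_cube_spec)
        dry = foreground_spectrum(0.20, wl, small_cube_spec)
        assert wet[i960] < dry[i960]

    def test_background_darker_than_foreground_at_685nm(self, noise_off_cube):
        wl = noise_off_cube["spec"].wavelengths()
        i = int(np.argmin(np.abs(wl - 685.5)))
        refl = (noise_off_cube["raw"].astype(float) - noise_off_cube["black"]) / (
            noise_off_cube["white"] - noise_off_cube["black"]
        )
        mask = noise_off_cube["mask"]
        assert refl[:, :, i][~mask].max() < refl[:, :, i][mask].min()

    def test_invalid_dims_rejected(self):
        with pytest.raises(ValueError):
            CubeSpec(height=0, width=10)


class TestEnose:
    def test_vector_length_is_10(self):
        assert generate_enose(0.5, rng=0).shape == (10,)

    def test_noise_off_deterministic_in_mc(self):
        a = generate_enose(0.37, noise=False)
        b = generate_enose(0.37, noise=False)
        assert np.array_equal(a, b)

    def test_sensors_monotone_in_moisture(self):
        # saturating response model: every sensor is rank-monotone in MC
        grid = np.linspace(0.1, 0.8, 40)
        responses = np.array([enose_response(m) for m in grid])
        for j in range(10):
            rho, _ = spearmanr(responses[:, j], grid)
            assert abs(rho) == pytest.approx(1.0)


class TestComputeMc:
    @pytest.mark.parametrize(
        "m1,m2,m3,expected", [(10, 20, 15, 0.5), (10, 20, 20, 0.0), (0, 4, 1, 0.75)]
    )
    def test_oven_drying_fraction(self, m1, m2, m3, expected):
        assert compute_mc(m1, m2, m3) == pytest.approx(expected)

    def test_degenerate_and_negative_loss_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            compute_mc(10, 10, 10)
        with pytest.raises(ValueError, match="egative"):
            compute_mc(10, 20, 21)


def test_dataset_write_roundtrip(tmp_path, small_cube_spec):
    from fusiondry import hsi_io

    ds = generate_dataset(
        DryingDesign(stage_times=(0, 6), replicates_per_stage=1),
        cube_spec=CubeSpec(height=16, width=16, n_bands=32),
        seed=3,
    )
    out = ds.write(tmp_path / "run", cube_format="hdf5")
    assert (out / "samples.csv").exists() and (out / "manifest.yaml").exists()
    data, wl, white, black = hsi_io.read_hdf5_cube(ds.samples[0].cube_path)
    raw, w, b, _ = ds.cube(0)
    assert np.allclose(data, raw)
    assert np.allclose(wl, np.linspace(397.66, 1003.81, 32))
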