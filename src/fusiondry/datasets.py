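"""Synthetic solar-drying experiment generator.

Emulates the statistical structure of a 13-stage shrimp drying study:
moisture content (MC) falling from ~72.75% (boiled) to ~15.67% (12 h),
hyperspectral reflectance cubes with moisture-linked absorption bands near
750 and 960 nm plus multiplicative/additive scattering artifacts, drying-
dependent darkening of the visible channels, and a 10-sensor metal-oxide
e-nose whose steady-state responses are saturating functions of a volatile
latent variable driven by MC.

Every random draw descends from a single integer seed via
``numpy.random.SeedSequence`` so datasets are reproducible bit-for-bit, and
all ground-truth parameters are recorded in a sidecar manifest so recovery
tests can read them back.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "DryingDesign",
    "DryingCurveParams",
    "CubeSpec",
    "EnoseSpec",
    "SampleRecord",
    "DryingDataset",
    "mc_curve",
    "foreground_spectrum",
    "generate_cube",
    "generate_enose",
    "generate_dataset",
    "compute_mc",
    "default_wavelengths",
]

#: Spectral axis limits (nm) and band count of the emulated line-scan camera.
WL_MIN_NM = 397.66
WL_MAX_NM = 1003.81
N_BANDS = 224


def default_wavelengths(n_bands: int = N_BANDS) -> np.ndarray:
    """Linearly spaced wavelength axis, 397.66-1003.81 nm."""
    return np.linspace(WL_MIN_NM, WL_MAX_NM, n_bands)


@dataclass(frozen=True)
class DryingDesign:
    """Sampling design: which drying stages, how many replicates each.

    Stage time 0 denotes the boiled (undried) product.
    """

    stage_times: tuple = tuple(range(13))  # hours: boiled + 1..12
    replicates_per_stage: int = 8
    seed: int = 0

    def __post_init__(self):
        times = np.asarray(self.stage_times, dtype=float)
        if times.size == 0 or np.any(np.diff(times) <= 0):
            raise ValueError("stage_times must be non-empty and strictly increasing")
        if np.any(times < 0):
            raise ValueError("stage_times must be nonnegative")
        if self.replicates_per_stage < 1:
            raise ValueError("replicates_per_stage must be >= 1")

    @property
    def n_samples(self) -> int:
        return len(self.stage_times) * self.replicates_per_stage


@dataclass(frozen=True)
class DryingCurveParams:
    """Two-phase drying curve: slow start, fast mid-phase, slow tail.

    The expected MC follows a normalized falling logistic anchored exactly at
    ``mc_start`` (t = 0) and ``mc_end`` (t = ``t_final``), with the drying
    rate peaking at ``inflection_h``.  Defaults reproduce the study anchors:
    72.75% boiled, 15.67% after 12 h, maximum rate near 4 h.
    """

    mc_start: float = 0.7275
    mc_end: float = 0.1567
    t_final: float = 12.0
    inflection_h: float = 4.0
    scale_h: float = 2.0
    replicate_sd: float = 0.012

    def __post_init__(self):
        if not (0.0 < self.mc_end < self.mc_start < 1.0):
            raise ValueError("require 0 < mc_end < mc_start < 1")
        if self.t_final <= 0 or self.scale_h <= 0:
            raise ValueError("t_final and scale_h must be positive")
        if self.replicate_sd < 0:
            raise ValueError("replicate_sd must be nonnegative")


def mc_curve(t, params: DryingCurveParams | None = None):
    """Expected moisture content (mass fraction) after ``t`` hours of drying.

    Deterministic, continuous and nonincreasing in ``t``; equals
    ``params.mc_start`` at t = 0 and ``params.mc_end`` at ``params.t_final``.
    """
    params = params or DryingCurveParams()
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0):
        raise ValueError("drying time must be nonnegative")

    def logistic(x):
        return 1.0 / (1.0 + np.exp((x - params.inflection_h) / params.scale_h))

    f0, fT = logistic(0.0), logistic(params.t_final)
    frac = (logistic(t_arr) - fT) / (f0 - fT)  # 1 at t=0, 0 at t_final
    mc = params.mc_end + (params.mc_start - params.mc_end) * frac
    return float(mc) if np.isscalar(t) else mc


@dataclass(frozen=True)
class CubeSpec:
    """Geometry and optics of a synthetic reflectance cube.

    The foreground is an ellipse of bright "tissue" spectra on a dark
    background.  The foreground spectrum is a smooth sigmoid baseline,
    darkened in the visible as the sample dries, minus Gaussian absorption
    bands at 750 and 960 nm whose depth increases with moisture.  Scattering
    is emulated by a per-sample multiplicative factor and additive offset
    (motivating SNV and derivative preprocessing downstream).
    """

    height: int = 96
    width: int = 96
    n_bands: int = N_BANDS
    # baseline reflectance: low in blue, high plateau in NIR
    base_low: float = 0.20
    base_high: float = 0.50
    base_center_nm: float = 550.0
    base_scale_nm: float = 70.0
    # water absorption bands (third/second O-H overtone region)
    band_centers_nm: tuple = (750.0, 960.0)
    band_sigmas_nm: tuple = (25.0, 30.0)
    band_amps: tuple = (0.35, 1.0)
    depth_offset: float = 0.05
    depth_slope: float = 0.35
    # visible darkening as drying proceeds (pigment concentration)
    darkening: float = 0.5
    vis_edge_nm: float = 700.0
    vis_width_nm: float = 30.0
    background_reflectance: float = 0.05
    # frame levels and artifacts
    white_level: float = 0.94
    black_level: float = 0.03
    scatter_mult_sd: float = 0.08
    offset_sd: float = 0.01
    noise_sd: float = 0.004
    ellipse_axes_frac: tuple = (0.36, 0.24)
    axis_jitter_frac: float = 0.05

    def __post_init__(self):
        if self.height <= 0 or self.width <= 0 or self.n_bands <= 0:
            raise ValueError("cube dimensions must be positive")
        if not self.black_level < self.white_level:
            raise ValueError("white level must exceed black level")

    def wavelengths(self) -> np.ndarray:
        return default_wavelengths(self.n_bands)


def foreground_spectrum(mc: float, wavelengths: np.ndarray, spec: CubeSpec) -> np.ndarray:
    """Closed-form noise-free tissue spectrum for a sample at moisture ``mc``.

    baseline(lambda) * (1 - darkening*(1-mc)*w_vis(lambda))
        - depth(mc) * sum_b amp_b * exp(-(lambda-c_b)^2 / (2 s_b^2))

    with depth(mc) = depth_offset + depth_slope*mc, strictly increasing in mc.
    """
    wl = np.asarray(wavelengths, dtype=float)
    baseline = spec.base_low + (spec.base_high - spec.base_low) / (
        1.0 + np.exp(-(wl - spec.base_center_nm) / spec.base_scale_nm)
    )
    w_vis = 1.0 / (1.0 + np.exp((wl - spec.vis_edge_nm) / spec.vis_width_nm))
    darkened = baseline * (1.0 - spec.darkening * (1.0 - mc) * w_vis)
    depth = spec.depth_offset + spec.depth_slope * mc
    bands = np.zeros_like(wl)
    for c, s, a in zip(spec.band_centers_nm, spec.band_sigmas_nm, spec.band_amps):
        bands += a * np.exp(-0.5 * ((wl - c) / s) ** 2)
    return darkened - depth * bands


def _ellipse_mask(spec: CubeSpec, rng: np.random.Generator | None) -> np.ndarray:
    h, w = spec.height, spec.width
    ay = spec.ellipse_axes_frac[0] * h
    ax = spec.ellipse_axes_frac[1] * w
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    if rng is not None and spec.axis_jitter_frac > 0:
        jit = rng.uniform(1 - spec.axis_jitter_frac, 1 + spec.axis_jitter_frac, size=2)
        ay, ax = ay * jit[0], ax * jit[1]
    yy, xx = np.mgrid[0:h, 0:w]
    return ((yy - cy) / ay) ** 2 + ((xx - cx) / ax) ** 2 <= 1.0


def generate_cube(
    mc: float,
    spec: CubeSpec | None = None,
    rng: np.random.Generator | int | None = None,
    noise: bool = True,
):
    """Generate one raw cube plus white/black reference frames.

    Returns ``(raw, white, black, mask)`` where ``raw`` is H x W x B float32,
    the frames broadcast against it, and ``mask`` is the ground-truth
    foreground.  With ``noise=False`` the calibrated foreground equals
    :func:`foreground_spectrum` exactly and the scattering factor/offset are
    1/0.
    """
    spec = spec or CubeSpec()
    rng = np.random.default_rng(rng)
    wl = spec.wavelengths()
    mask = _ellipse_mask(spec, rng if noise else None)

    fg = foreground_spectrum(mc, wl, spec)
    refl = np.empty((spec.height, spec.width, spec.n_bands), dtype=np.float64)
    refl[:] = spec.background_reflectance
    if noise:
        mult = 1.0 + spec.scatter_mult_sd * rng.standard_normal()
        offset = spec.offset_sd * rng.standard_normal()
        refl[mask] = mult * fg + offset
        refl += spec.noise_sd * rng.standard_normal(refl.shape)
    else:
        refl[mask] = fg

    white = np.full(spec.n_bands, spec.white_level, dtype=np.float64)
    black = np.full(spec.n_bands, spec.black_level, dtype=np.float64)
    raw = black + refl * (white - black)
    return raw.astype(np.float32), white, black, mask


@dataclass(frozen=True)
class EnoseSpec:
    """Ten metal-oxide sensors responding to a drying-driven volatile latent.

    The latent volatile intensity is v = 1 - mc (flavor compounds concentrate
    as water leaves).  Sensor i responds base_i + amp_i * v / (K_i + v) — a
    monotone saturating (Michaelis-Menten) curve; some amplitudes are
    negative (reducing-gas sensors).  Per-sample gain drift is multiplicative.
    """

    amps: tuple = (1.8, -0.9, 1.2, 0.7, -0.5, 1.5, 0.4, -1.1, 0.9, 0.6)
    half_sats: tuple = (0.3, 0.5, 0.2, 0.8, 0.4, 0.6, 0.25, 0.35, 0.7, 0.45)
    baselines: tuple = (1.0, 2.0, 1.5, 1.2, 1.8, 1.1, 1.4, 2.2, 1.3, 1.6)
    drift_sd: float = 0.015
    noise_sd: float = 0.01

    def __post_init__(self):
        if not (len(self.amps) == len(self.half_sats) == len(self.baselines) == 10):
            raise ValueError("exactly 10 sensors are modeled")

    @property
    def n_sensors(self) -> int:
        return 10


def enose_response(mc: float, spec: EnoseSpec | None = None) -> np.ndarray:
    """Deterministic (drift- and noise-free) 10-sensor response at moisture ``mc``."""
    spec = spec or EnoseSpec()
    v = 1.0 - mc
    amps = np.asarray(spec.amps)
    ks = np.asarray(spec.half_sats)
    base = np.asarray(spec.baselines)
    return base + amps * v / (ks + v)


def generate_enose(
    mc: float,
    spec: EnoseSpec | None = None,
    rng: np.random.Generator | int | None = None,
    noise: bool = True,
) -> np.ndarray:
    """One 10-vector of steady-state sensor responses (conductance-ratio units)."""
    spec = spec or EnoseSpec()
    resp = enose_response(mc, spec)
    if noise:
        rng = np.random.default_rng(rng)
        gain = 1.0 + spec.drift_sd * rng.standard_normal(spec.n_sensors)
        resp = resp * gain + spec.noise_sd * rng.standard_normal(spec.n_sensors)
    return resp


@dataclass
class SampleRecord:
    """One sample: identity, drying stage, ground truth, measurements."""

    sample_id: str
    stage_time: float
    mc_true: float
    enose: np.ndarray
    cube_seed: int | None = None
    cube_path: str | None = None

    def __post_init__(self):
        self.enose = np.asarray(self.enose, dtype=float)
        if self.enose.shape != (10,):
            raise ValueError("enose must be a length-10 vector")
        if not 0.0 <= self.mc_true <= 1.0:
            raise ValueError("mc_true must lie in [0, 1]")


@dataclass
class DryingDataset:
    """A generated drying experiment: records plus the specs that made them.

    Cubes are materialized lazily from per-sample seeds (a 96x96x224 cube is
    ~8 MB; 104 of them need not coexist in memory).
    """

    samples: list
    design: DryingDesign
    curve: DryingCurveParams
    cube_spec: CubeSpec
    enose_spec: EnoseSpec
    seed: int
    noise: bool = True

    def __len__(self):
        return len(self.samples)

    @property
    def mc(self) -> np.ndarray:
        return np.array([s.mc_true for s in self.samples])

    @property
    def stage_times(self) -> np.ndarray:
        return np.array([s.stage_time for s in self.samples])

    def enose_matrix(self) -> np.ndarray:
        return np.stack([s.enose for s in self.samples])

    def cube(self, i: int):
        """Materialize (raw, white, black, true_mask) for sample ``i``."""
        s = self.samples[i]
        rng = np.random.default_rng(s.cube_seed)
        return generate_cube(s.mc_true, self.cube_spec, rng, noise=self.noise)

    def sample_table(self) -> pd.DataFrame:
        rows = []
        for s in self.samples:
            row = {"sample_id": s.sample_id, "stage_h": s.stage_time, "mc_true": s.mc_true}
            row.update({f"S{k + 1}": s.enose[k] for k in range(10)})
            rows.append(row)
        return pd.DataFrame(rows)

    def manifest(self) -> dict:
        return {
            "seed": int(self.seed),
            "noise": bool(self.noise),
            "design": dataclasses.asdict(self.design),
            "curve": dataclasses.asdict(self.curve),
            "cube_spec": dataclasses.asdict(self.cube_spec),
            "enose_spec": dataclasses.asdict(self.enose_spec),
            "n_samples": len(self.samples),
        }

    def write(self, out_dir, cube_format: str = "hdf5") -> Path:
        """Write sample/e-nose CSV, YAML manifest and per-sample cubes."""
        from . import hsi_io

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.sample_table().to_csv(out / "samples.csv", index=False)
        with open(out / "manifest.yaml", "w") as fh:
            yaml.safe_dump(self.manifest(), fh, sort_keys=False)
        wl = self.cube_spec.wavelengths()
        cube_dir = out / "cubes"
        cube_dir.mkdir(exist_ok=True)
        for i, s in enumerate(self.samples):
            raw, white, black, _ = self.cube(i)
            if cube_format == "hdf5":
                path = cube_dir / f"{s.sample_id}.h5"
                hsi_io.write_hdf5_cube(path, raw, wl, white=white, black=black)
            elif cube_format == "envi":
                path = cube_dir / f"{s.sample_id}.hdr"
                hsi_io.write_envi(path, raw, wl)
            else:
                raise ValueError(f"unknown cube format: {cube_format!r}")
            s.cube_path = str(path)
        self.sample_table().to_csv(out / "samples.csv", index=False)
        return out


def generate_dataset(
    design: DryingDesign | None = None,
    curve: DryingCurveParams | None = None,
    cube_spec: CubeSpec | None = None,
    enose_spec: EnoseSpec | None = None,
    seed: int | None = None,
    noise: bool = True,
) -> DryingDataset:
    """Generate a full drying experiment (default: 13 stages x 8 = 104 samples).

    The same seed yields a bit-identical dataset, including the lazily
    materialized cubes.
    """
    design = design or DryingDesign()
    curve = curve or DryingCurveParams()
    cube_spec = cube_spec or CubeSpec()
    enose_spec = enose_spec or EnoseSpec()
    if seed is None:
        seed = design.seed

    root = np.random.SeedSequence(seed)
    samples = []
    for t in design.stage_times:
        mc_mean = mc_curve(float(t), curve)
        for r in range(design.replicates_per_stage):
            child = root.spawn(1)[0]
            rng = np.random.default_rng(child)
            if noise and curve.replicate_sd > 0:
                mc = float(np.clip(mc_mean + curve.replicate_sd * rng.standard_normal(), 0.0, 1.0))
            else:
                mc = mc_mean
            cube_seed = int(rng.integers(0, 2**31 - 1))
            enose = generate_enose(mc, enose_spec, rng, noise=noise)
            samples.append(
                SampleRecord(
                    sample_id=f"t{t:g}h_r{r + 1}",
                    stage_time=float(t),
                    mc_true=mc,
                    enose=enose,
                    cube_seed=cube_seed,
                )
            )
    return DryingDataset(samples, design, curve, cube_spec, enose_spec, seed, noise)


def compute_mc(m1: float, m2: float, m3: float) -> float:
    """Oven-drying moisture content (m2 - m3) / (m2 - m1), as a mass fraction.

    m1: bottle mass (g); m2: bottle + wet sample; m3: bottle + dried sample.
    """
    if m2 <= m1:
        raise ValueError("degenerate sample mass: m2 must exceed m1 (empty bottle)")
    if m3 > m2:
        raise ValueError("negative mass loss: m3 exceeds m2")
    return (m2 - m3) / (m2 - m1)
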