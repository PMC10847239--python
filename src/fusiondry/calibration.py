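"""Reflectance calibration, ROI segmentation and spectrum extraction.

Raw line-scan counts are converted to reflectance with the standard
black-and-white correction R = (raw - black) / (white - black), the sample
foreground is segmented by Otsu thresholding the band nearest 685.5 nm (the
wavelength of maximum sample/background contrast), and per-sample spectra
are ROI means.  RGB composites use the bands nearest 647 / 550 / 460 nm.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage.filters import threshold_otsu
from skimage.measure import label

__all__ = [
    "HyperspectralCube",
    "CalibrationError",
    "SegmentationError",
    "reflectance_correct",
    "nearest_band",
    "segment_roi",
    "mean_spectrum",
    "rgb_composite",
    "SEGMENTATION_NM",
    "RGB_NM",
]

#: Segmentation wavelength: maximum foreground/background reflectance contrast.
SEGMENTATION_NM = 685.5
#: Wavelengths (nm) used for the R, G, B channels of the composite.
RGB_NM = (647.0, 550.0, 460.0)


class CalibrationError(ValueError):
    pass


class SegmentationError(RuntimeError):
    pass


@dataclass
class HyperspectralCube:
    """Reflectance cube: H x W x B data plus a strictly increasing nm axis."""

    data: np.ndarray
    wavelengths: np.ndarray
    clip_fraction: float = 0.0

    def __post_init__(self):
        self.data = np.asarray(self.data)
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("cube data must be H x W x B")
        if self.data.shape[2] != self.wavelengths.size:
            raise ValueError("band count must match wavelength axis length")
        if np.any(np.diff(self.wavelengths) <= 0):
            raise ValueError("wavelength axis must be strictly increasing")

    @property
    def shape(self):
        return self.data.shape

    def band(self, index: int) -> np.ndarray:
        return self.data[:, :, index]


def reflectance_correct(
    raw_cube,
    white_frame,
    black_frame,
    wavelengths=None,
    clip=(0.0, 1.5),
    eps: float = 1e-6,
    max_clip_fraction: float = 0.05,
) -> HyperspectralCube:
    """Black-and-white correction R = (raw - black) / (white - black).

    ``white_frame``/``black_frame`` may be per-band vectors or full frames
    broadcastable against ``raw_cube``.  Values are clipped to ``clip`` and
    the clipped fraction recorded; more than ``max_clip_fraction`` clipped
    pixels, or a white-black gap below ``eps`` anywhere, raises
    :class:`CalibrationError` naming the offending bands.
    """
    raw = np.asarray(raw_cube, dtype=np.float64)
    white = np.broadcast_to(np.asarray(white_frame, dtype=np.float64), raw.shape)
    black = np.broadcast_to(np.asarray(black_frame, dtype=np.float64), raw.shape)
    denom = white - black
    bad = denom < eps
    if np.any(bad):
        bad_bands = np.unique(np.nonzero(bad)[2])
        raise CalibrationError(
            f"white-black gap below {eps} in band(s) {bad_bands.tolist()[:10]}"
        )
    refl = (raw - black) / denom
    clipped = (refl < clip[0]) | (refl > clip[1])
    frac = float(clipped.mean())
    if frac > max_clip_fraction:
        raise CalibrationError(
            f"{frac:.1%} of pixels fall outside {clip} after correction "
            f"(limit {max_clip_fraction:.0%}); check reference frames"
        )
    refl = np.clip(refl, clip[0], clip[1])
    if wavelengths is None:
        from .datasets import default_wavelengths

        wavelengths = default_wavelengths(raw.shape[2])
    return HyperspectralCube(refl, wavelengths, clip_fraction=frac)


def nearest_band(cube_or_wavelengths, target_nm: float) -> int:
    """Index of the band nearest ``target_nm``; ties break toward the lower index.

    Targets outside the axis range by more than half the local spacing are
    rejected.
    """
    wl = getattr(cube_or_wavelengths, "wavelengths", cube_or_wavelengths)
    wl = np.asarray(wl, dtype=float)
    spacing = np.diff(wl)
    lo = wl[0] - spacing[0] / 2 if spacing.size else wl[0]
    hi = wl[-1] + spacing[-1] / 2 if spacing.size else wl[-1]
    if not (lo <= target_nm <= hi):
        raise ValueError(f"target {target_nm} nm outside axis range [{wl[0]}, {wl[-1]}]")
    # argmin returns the first (lower) index on exact ties
    return int(np.argmin(np.abs(wl - target_nm)))


def segment_roi(cube: HyperspectralCube, target_nm: float = SEGMENTATION_NM) -> np.ndarray:
    """Otsu-threshold the band nearest ``target_nm``; keep the brighter side's
    largest connected component as the sample foreground."""
    band = cube.band(nearest_band(cube, target_nm))
    if np.ptp(band) == 0:
        raise SegmentationError("segmentation failed: constant image, no contrast")
    thresh = threshold_otsu(band)
    fg = band > thresh
    # foreground = side with the higher mean reflectance
    if fg.any() and (~fg).any() and band[fg].mean() < band[~fg].mean():
        fg = ~fg
    if not fg.any():
        raise SegmentationError("segmentation failed: empty foreground")
    labels = label(fg, connectivity=2)
    counts = np.bincount(labels.ravel())
    counts[0] = 0
    return labels == int(np.argmax(counts))


def mean_spectrum(cube: HyperspectralCube, mask: np.ndarray) -> np.ndarray:
    """Per-band arithmetic mean of reflectance over foreground pixels."""
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != cube.shape[:2]:
        raise ValueError("mask shape must match cube spatial dimensions")
    if not mask.any():
        raise ValueError("empty ROI mask")
    return cube.data[mask].mean(axis=0)


def rgb_composite(cube: HyperspectralCube, rgb_nm=RGB_NM) -> np.ndarray:
    """H x W x 3 composite from the bands nearest 647, 550 and 460 nm, in [0, 1]."""
    idx = [nearest_band(cube, nm) for nm in rgb_nm]
    return np.clip(cube.data[:, :, idx], 0.0, 1.0)
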