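"""Image variables: 18 color moments plus 8 GLCM texture statistics (26 total).

Color moments are the first three moments (mean, population SD, signed cube
root of the third central moment) of the R, G, B, H, S, V channel
distributions over the masked sample.  Texture is measured on the first two
principal-component score images of the masked spectral cube: four
direction-averaged Haralick statistics (contrast, correlation, energy,
homogeneity) from a symmetric normalized co-occurrence matrix at distance 1,
directions 0/45/90/135 degrees, counting only pixel pairs with both ends
inside the mask.
"""

from __future__ import annotations

import numpy as np
from skimage.color import rgb2hsv
from skimage.feature import graycomatrix
from sklearn.decomposition import PCA

from .calibration import HyperspectralCube, rgb_composite

__all__ = [
    "color_moments",
    "pca_score_images",
    "glcm_features",
    "image_feature_vector",
    "COLOR_MOMENT_LABELS",
    "TEXTURE_LABELS",
    "IMAGE_FEATURE_LABELS",
]

_CHANNELS = ("R", "G", "B", "H", "S", "V")
_MOMENTS = ("mean", "sd", "skew")
_GLCM_STATS = ("contrast", "correlation", "energy", "homogeneity")

COLOR_MOMENT_LABELS = tuple(f"{m}_{c}" for m in _MOMENTS for c in _CHANNELS)
TEXTURE_LABELS = tuple(f"{s}_PC{k}" for k in (1, 2) for s in _GLCM_STATS)
IMAGE_FEATURE_LABELS = COLOR_MOMENT_LABELS + TEXTURE_LABELS

# offsets (drow, dcol) for 0, 45, 90, 135 degrees at distance d
_DIRECTIONS = ((0, 1), (-1, 1), (-1, 0), (-1, -1))


def color_moments(rgb_image: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """18 color moments over the masked pixels, moments-major order.

    Channels are R, G, B plus H, S, V from the RGB->HSV conversion (all on
    [0, 1]); per channel: mean, population standard deviation, and the signed
    cube root of the third central moment (the color-moment skewness
    convention).
    """
    rgb = np.asarray(rgb_image, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if rgb.ndim != 3 or rgb.shape[2] != 3:
        raise ValueError("rgb_image must be H x W x 3")
    if not mask.any():
        raise ValueError("empty mask")
    px_rgb = rgb[mask]  # n x 3
    px_hsv = rgb2hsv(px_rgb[None, :, :])[0]
    px = np.hstack([px_rgb, px_hsv])  # n x 6
    mean = px.mean(axis=0)
    centered = px - mean
    sd = np.sqrt((centered**2).mean(axis=0))
    m3 = (centered**3).mean(axis=0)
    # cbrt amplifies rounding noise: a third moment negligible against sd^3
    # is genuinely zero (symmetric distribution)
    m3[np.abs(m3) < 1e-12 * np.maximum(sd, 1e-6) ** 3] = 0.0
    skew = np.cbrt(m3)
    return np.concatenate([mean, sd, skew])


def pca_score_images(cube: HyperspectralCube, mask: np.ndarray, cum_var: float = 0.99):
    """Principal-component score images of the masked spectral cube.

    PCA treats bands as variables over the foreground pixels (mean-centered,
    unscaled).  Retains the smallest k with cumulative explained variance >=
    ``cum_var`` but never fewer than 2 components; each score image is
    min-max rescaled to [0, 1] over the mask and painted back onto the grid
    with background 0.

    Returns ``(score_images, explained_variance_ratio)``.
    """
    mask = np.asarray(mask, dtype=bool)
    px = cube.data[mask]
    if px.shape[0] < 2:
        raise ValueError("need at least 2 foreground pixels for PCA")
    if np.allclose(px.var(axis=0), 0):
        raise ValueError("degenerate foreground: zero variance in every band")
    n_max = min(px.shape[0] - 1, px.shape[1])
    pca = PCA(n_components=n_max, svd_solver="full")
    scores = pca.fit_transform(px)
    ratios = pca.explained_variance_ratio_
    k = int(np.searchsorted(np.cumsum(ratios), cum_var) + 1)
    k = max(2, min(k, n_max))
    images = []
    for j in range(k):
        s = scores[:, j]
        rng = np.ptp(s)
        s01 = (s - s.min()) / rng if rng > 0 else np.zeros_like(s)
        img = np.zeros(mask.shape, dtype=float)
        img[mask] = s01
        images.append(img)
    return images, ratios[:k]


def _quantize(gray: np.ndarray, mask: np.ndarray, levels: int) -> np.ndarray:
    vals = gray[mask]
    lo, hi = vals.min(), vals.max()
    q = np.zeros(gray.shape, dtype=np.uint16)
    if hi > lo:
        q[mask] = np.minimum(
            ((gray[mask] - lo) / (hi - lo) * levels).astype(np.uint16), levels - 1
        )
    return q


def glcm_features(
    gray_image: np.ndarray,
    mask: np.ndarray,
    levels: int = 32,
    d: int = 1,
    angles=(0.0, np.pi / 4, np.pi / 2, 3 * np.pi / 4),
) -> np.ndarray:
    """Direction-averaged (contrast, correlation, energy, homogeneity).

    The image is min-max quantized to ``levels`` gray levels over the mask;
    for each of the four directions a symmetric co-occurrence matrix is
    accumulated over pixel pairs with both ends in the mask, normalized, and
    the four statistics computed; the result is the average over directions.
    Correlation of a zero-variance (single-level) region is defined as 0.
    """
    gray = np.asarray(gray_image, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty mask")
    q = _quantize(gray, mask, levels)
    # reserve one extra level for background so masked-out pairs can be dropped
    q_bg = np.where(mask, q, levels).astype(np.uint8 if levels < 255 else np.uint16)
    glcm = graycomatrix(
        q_bg,
        distances=[d],
        angles=list(angles),
        levels=levels + 1,
        symmetric=True,
        normed=False,
    )
    per_direction = []
    for a in range(len(angles)):
        P = glcm[:levels, :levels, 0, a].astype(float)
        total = P.sum()
        if total == 0:
            continue
        P /= total
        i = np.arange(levels, dtype=float)
        diff2 = (i[:, None] - i[None, :]) ** 2
        contrast = float((P * diff2).sum())
        energy = float((P**2).sum())
        homogeneity = float((P / (1.0 + diff2)).sum())
        pi = P.sum(axis=1)
        mu = float((i * pi).sum())
        var = float(((i - mu) ** 2 * pi).sum())
        if var > 0:
            corr = float((P * (i[:, None] - mu) * (i[None, :] - mu)).sum() / var)
        else:
            corr = 0.0
        per_direction.append((contrast, corr, energy, homogeneity))
    if not per_direction:
        raise ValueError("mask contains no valid pixel pairs at distance d")
    return np.mean(per_direction, axis=0)


def image_feature_vector(cube: HyperspectralCube, mask: np.ndarray, levels: int = 32):
    """The 26 image variables: 18 color moments then 4 GLCM stats x {PC1, PC2}.

    Returns ``(values, labels)`` with a stable deterministic ordering.
    """
    rgb = rgb_composite(cube)
    cm = color_moments(rgb, mask)
    score_images, _ = pca_score_images(cube, mask)
    tex = np.concatenate(
        [glcm_features(score_images[j], mask, levels=levels) for j in (0, 1)]
    )
    return np.concatenate([cm, tex]), list(IMAGE_FEATURE_LABELS)
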