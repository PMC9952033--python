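"""Nodule descriptors: GLCM texture, shape, intensity and geometric features.

All features are computed on a grayscale image restricted to a binary region
of interest (the nodule mask).  Texture comes from a masked gray-level
co-occurrence matrix; shape and geometric descriptors are computed on the
mask alone (translation invariant); intensity statistics are plain moments of
the masked pixel values.  The geometric block includes the radial distance
signature r(theta) -- centroid-to-boundary distance per ray -- whose
coefficient of variation ("roughness") is the main spiculation cue separating
irregular malignant nodules from smooth benign ones.
"""

from __future__ import annotations

from dataclasses import dataclass, fields

import numpy as np
import scipy.ndimage as ndi
from skimage import measure
from skimage.filters import threshold_otsu

from .imageprep import as_gray_image

__all__ = [
    "FeatureVector",
    "FEATURE_NAMES",
    "as_roi_mask",
    "auto_mask",
    "texture_features",
    "shape_features",
    "intensity_features",
    "geometric_features",
    "extract_features",
]

_GLCM_OFFSETS = ((0, 1), (1, 0), (1, 1), (1, -1))
_N_RAYS = 360


@dataclass(frozen=True)
class FeatureVector:
    """The full descriptor bank for one ROI, in documented order."""

    # texture
    contrast: float
    correlation: float
    homogeneity: float
    sum_of_square_variance: float
    entropy: float
    spectral: float
    spatial: float
    # shape
    area: float
    perimeter: float
    circularity: float
    roundness: float
    irregularity: float
    # intensity
    intensity_sum: float
    mean: float
    std_variance: float
    kurtosis: float
    skewness: float
    median: float
    # geometric
    eccentricity: float
    compactness: float
    roughness: float
    laii: float
    radial_mean: float
    radial_std: float

    def to_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in FEATURE_NAMES])


FEATURE_NAMES: tuple[str, ...] = tuple(f.name for f in fields(FeatureVector))


def as_roi_mask(mask, image_shape: tuple[int, int] | None = None) -> np.ndarray:
    """Validate a binary ROI mask; keep the largest 8-connected component.

    Requires at least 16 foreground pixels (after component selection).
    """
    m = np.asarray(mask)
    if m.ndim != 2:
        raise ValueError(f"mask must be 2-D, got shape {m.shape}")
    if image_shape is not None and m.shape != tuple(image_shape):
        raise ValueError(f"mask shape {m.shape} differs from image shape {image_shape}")
    m = m.astype(bool)
    labels, n = ndi.label(m, structure=np.ones((3, 3), dtype=int))
    if n == 0:
        raise ValueError("mask has no foreground pixels")
    if n > 1:
        sizes = ndi.sum_labels(m, labels, index=np.arange(1, n + 1))
        m = labels == (1 + int(np.argmax(sizes)))
    if m.sum() < 16:
        raise ValueError(f"mask must have >= 16 foreground pixels, got {int(m.sum())}")
    return m


def auto_mask(image) -> np.ndarray:
    """Convenience fallback mask: Otsu threshold plus largest component."""
    img = as_gray_image(image)
    return as_roi_mask(img > threshold_otsu(img))


def _masked_glcm(quantized: np.ndarray, mask: np.ndarray, levels: int) -> np.ndarray:
    """Symmetric normalized co-occurrence matrix averaged over the 4 offsets.

    Only pixel pairs with both ends inside the mask contribute; offsets that
    produce no in-mask pair are skipped.
    """
    mats = []
    for dr, dc in _GLCM_OFFSETS:
        h, w = quantized.shape
        r0, r1 = max(0, -dr), min(h, h - dr)
        c0, c1 = max(0, -dc), min(w, w - dc)
        a = quantized[r0:r1, c0:c1]
        b = quantized[r0 + dr : r1 + dr, c0 + dc : c1 + dc]
        ok = mask[r0:r1, c0:c1] & mask[r0 + dr : r1 + dr, c0 + dc : c1 + dc]
        if not ok.any():
            continue
        counts = np.zeros((levels, levels))
        np.add.at(counts, (a[ok], b[ok]), 1.0)
        counts += counts.T  # symmetric
        mats.append(counts / counts.sum())
    if not mats:
        raise ValueError("ROI too thin: no co-occurring in-mask pixel pairs")
    return np.mean(mats, axis=0)


def texture_features(image, mask, levels: int = 32) -> dict[str, float]:
    """GLCM texture statistics plus spectral and spatial descriptors.

    Intensities inside the ROI bounding box are quantized to ``levels`` bins
    over the ROI min-max range.  A constant ROI yields contrast 0,
    homogeneity 1, entropy 0 and correlation 0 (zero-variance convention).
    ``spectral`` is the fraction of ROI power-spectrum energy outside the
    lowest radial-frequency quartile; ``spatial`` is the lag-1 normalized
    spatial autocorrelation of the masked intensities.
    """
    img = as_gray_image(image)
    m = as_roi_mask(mask, img.shape)
    rows, cols = np.nonzero(m)
    box = (slice(rows.min(), rows.max() + 1), slice(cols.min(), cols.max() + 1))
    sub, msub = img[box], m[box]
    vals = sub[msub]
    lo, hi = vals.min(), vals.max()

    if hi == lo:
        glcm_stats = dict(
            contrast=0.0, correlation=0.0, homogeneity=1.0,
            sum_of_square_variance=0.0, entropy=0.0,
        )
    else:
        q = np.clip(((sub - lo) / (hi - lo) * levels).astype(int), 0, levels - 1)
        p = _masked_glcm(q, msub, levels)
        i, j = np.meshgrid(np.arange(levels), np.arange(levels), indexing="ij")
        contrast = float(np.sum((i - j) ** 2 * p))
        pi = p.sum(axis=1)
        mu = float(np.sum(np.arange(levels) * pi))
        var = float(np.sum((np.arange(levels) - mu) ** 2 * pi))
        if var > 0:
            correlation = float(np.sum((i - mu) * (j - mu) * p)) / var
        else:
            correlation = 0.0
        homogeneity = float(np.sum(p / (1.0 + np.abs(i - j))))
        ssv = float(np.sum((i - mu) ** 2 * p))
        nz = p[p > 0]
        entropy = float(-np.sum(nz * np.log2(nz)))
        glcm_stats = dict(
            contrast=contrast, correlation=correlation, homogeneity=homogeneity,
            sum_of_square_variance=ssv, entropy=entropy,
        )

    glcm_stats["spectral"] = _spectral_energy_fraction(sub, msub)
    glcm_stats["spatial"] = _lag1_autocorrelation(sub, msub)
    return glcm_stats


def _spectral_energy_fraction(sub: np.ndarray, msub: np.ndarray) -> float:
    vals = sub[msub]
    filled = np.where(msub, sub, vals.mean()) - vals.mean()
    power = np.abs(np.fft.fft2(filled)) ** 2
    fy = np.fft.fftfreq(sub.shape[0])[:, None]
    fx = np.fft.fftfreq(sub.shape[1])[None, :]
    r = np.hypot(fy, fx)
    total = power.sum()
    if total == 0:
        return 0.0
    return float(power[r > r.max() / 4].sum() / total)


def _lag1_autocorrelation(sub: np.ndarray, msub: np.ndarray) -> float:
    vals = sub[msub]
    mu, var = vals.mean(), vals.var()
    if var == 0:
        return 0.0
    num, n_pairs = 0.0, 0
    dev = sub - mu
    for dr, dc in ((0, 1), (1, 0)):
        a = dev[: sub.shape[0] - dr, : sub.shape[1] - dc]
        b = dev[dr:, dc:]
        ok = msub[: sub.shape[0] - dr, : sub.shape[1] - dc] & msub[dr:, dc:]
        num += float((a * b)[ok].sum())
        n_pairs += int(ok.sum())
    if n_pairs == 0:
        return 0.0
    return num / (n_pairs * var)


def _region_props(m: np.ndarray):
    return measure.regionprops(m.astype(np.uint8))[0]


def shape_features(mask) -> dict[str, float]:
    """Area, perimeter, circularity = 4 pi A / P^2, irregularity, roundness."""
    m = as_roi_mask(mask)
    area = float(m.sum())
    perimeter = float(measure.perimeter(m))
    if perimeter <= 0:
        raise ValueError("degenerate mask: zero perimeter")
    props = _region_props(m)
    major = props.axis_major_length
    circularity = 4 * np.pi * area / perimeter**2
    return dict(
        area=area,
        perimeter=perimeter,
        circularity=circularity,
        roundness=4 * area / (np.pi * major**2) if major > 0 else 0.0,
        irregularity=1.0 / circularity,
    )


def intensity_features(image, mask) -> dict[str, float]:
    """First-order statistics of the masked intensities.

    Variance is the population variance; kurtosis is excess kurtosis; a
    zero-variance ROI reports skewness 0 and kurtosis 0 by convention.
    """
    img = as_gray_image(image)
    m = as_roi_mask(mask, img.shape)
    v = img[m]
    mu = float(v.mean())
    m2 = float(np.mean((v - mu) ** 2))
    if m2 > 0:
        m3 = float(np.mean((v - mu) ** 3))
        m4 = float(np.mean((v - mu) ** 4))
        skew, kurt = m3 / m2**1.5, m4 / m2**2 - 3.0
    else:
        skew = kurt = 0.0
    return dict(
        intensity_sum=float(v.sum()),
        mean=mu,
        std_variance=m2,
        kurtosis=kurt,
        skewness=skew,
        median=float(np.median(v)),
    )


def radial_signature(mask, n_rays: int = _N_RAYS) -> np.ndarray:
    """Centroid-to-boundary distance sampled at ``n_rays`` uniform angles.

    Each ray is marched outward from the centroid in half-pixel steps; the
    farthest in-mask sample gives r(theta).  Raises if the centroid lies
    outside the region or some ray never meets it.
    """
    m = as_roi_mask(mask)
    rows, cols = np.nonzero(m)
    cy, cx = rows.mean(), cols.mean()
    if not m[int(round(cy)), int(round(cx))]:
        raise ValueError("centroid lies outside the region (non-star-shaped mask)")
    r_max = float(np.hypot(rows - cy, cols - cx).max()) + 1.0
    theta = np.linspace(0, 2 * np.pi, n_rays, endpoint=False)
    steps = np.arange(0, r_max, 0.5)
    yy = np.clip(np.rint(cy + steps[None, :] * np.sin(theta)[:, None]), 0, m.shape[0] - 1).astype(int)
    xx = np.clip(np.rint(cx + steps[None, :] * np.cos(theta)[:, None]), 0, m.shape[1] - 1).astype(int)
    inside = m[yy, xx]  # (n_rays, n_steps)
    if not inside.any(axis=1).all():
        raise ValueError("some ray never intersects the region")
    last = inside.shape[1] - 1 - np.argmax(inside[:, ::-1], axis=1)
    return steps[last]


def geometric_features(mask, laii_radius: int = 5) -> dict[str, float]:
    """Moment eccentricity, compactness, radial-signature and boundary stats.

    ``laii`` (local area integral invariant) is the mean, over boundary
    pixels, of the fraction of a radius-``laii_radius`` disk lying inside the
    mask: 0.5 along a straight edge, below 0.5 at spikes.
    """
    m = as_roi_mask(mask)
    props = _region_props(m)
    area = float(m.sum())
    perimeter = float(measure.perimeter(m))
    sig = radial_signature(m)
    r_mean, r_std = float(sig.mean()), float(sig.std())

    # disk-occupancy fraction at boundary pixels
    r = laii_radius
    yy, xx = np.mgrid[-r : r + 1, -r : r + 1]
    disk = (yy**2 + xx**2 <= r**2).astype(float)
    occupancy = ndi.convolve(m.astype(float), disk, mode="constant") / disk.sum()
    boundary = m & ~ndi.binary_erosion(m)
    laii = float(occupancy[boundary].mean())

    return dict(
        eccentricity=float(props.eccentricity),
        compactness=perimeter**2 / area,
        roughness=r_std / r_mean if r_mean > 0 else 0.0,
        laii=laii,
        radial_mean=r_mean,
        radial_std=r_std,
    )


def extract_features(image, mask, levels: int = 32, laii_radius: int = 5) -> FeatureVector:
    """Compute the full 24-feature descriptor bank for one image + ROI mask."""
    img = as_gray_image(image)
    m = as_roi_mask(mask, img.shape)
    parts: dict[str, float] = {}
    parts.update(texture_features(img, m, levels=levels))
    parts.update(shape_features(m))
    parts.update(intensity_features(img, m))
    parts.update(geometric_features(m, laii_radius=laii_radius))
    return FeatureVector(**parts)
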