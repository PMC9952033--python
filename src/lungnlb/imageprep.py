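"""Image I/O, median filtering, min-max normalization, noise injection, PSNR.

All in-memory images are 2-D float64 numpy arrays ("gray images").  Files are
read preserving the stored bit depth's scale (an 8-bit PNG yields values in
[0, 255], a 16-bit TIFF in [0, 65535]); every downstream computation is done
in floating point and values are only quantized again at export time.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import numpy as np
import pydicom
import scipy.ndimage as ndi
from imageio import v3 as iio
from skimage.metrics import peak_signal_noise_ratio

__all__ = [
    "NoiseSpec",
    "NormSpec",
    "as_gray_image",
    "read_gray",
    "write_gray",
    "median_filter",
    "normalize",
    "add_gaussian_noise",
    "psnr",
]

# ITU-R BT.601 luminance weights, used to collapse RGB(A) inputs.
_LUMA = np.array([0.299, 0.587, 0.114])


@dataclass(frozen=True)
class NoiseSpec:
    """Additive white Gaussian noise: a = a0 + n, n ~ N(0, sigma^2)."""

    sigma: float
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValueError(f"sigma must be >= 0, got {self.sigma}")


@dataclass(frozen=True)
class NormSpec:
    """Target intensity range [a_new, b_new] for min-max normalization."""

    a_new: float = 0.0
    b_new: float = 255.0

    def __post_init__(self) -> None:
        if not self.b_new > self.a_new:
            raise ValueError(f"b_new must exceed a_new, got [{self.a_new}, {self.b_new}]")


def as_gray_image(pixels, min_side: int = 8) -> np.ndarray:
    """Validate and return a 2-D float64 image array.

    Raises ``ValueError`` for non-2-D input, non-finite values, or a side
    shorter than ``min_side`` (images must accommodate the largest patch).
    """
    arr = np.asarray(pixels, dtype=np.float64)
    if arr.ndim != 2:
        raise ValueError(f"expected a 2-D image, got shape {arr.shape}")
    if arr.shape[0] < min_side or arr.shape[1] < min_side:
        raise ValueError(f"image sides must be >= {min_side}, got shape {arr.shape}")
    if not np.isfinite(arr).all():
        raise ValueError("image contains non-finite values")
    return arr


def read_gray(path: str | os.PathLike) -> np.ndarray:
    """Read a PNG/TIFF (8/16-bit) or single-frame DICOM file as a gray image.

    Stored integer values are preserved without rescaling.  Multi-channel
    inputs are reduced to one channel by BT.601 luminance weighting; an alpha
    channel, if present, is dropped.
    """
    path = os.fspath(path)
    if not os.path.exists(path):
        raise IOError(f"no such file: {path}")
    if path.lower().endswith((".dcm", ".dicom")):
        ds = pydicom.dcmread(path)
        arr = ds.pixel_array
        if arr.ndim != 2:
            raise ValueError(f"only single-frame 2-D DICOM is supported, got shape {arr.shape}")
        return as_gray_image(arr)
    arr = iio.imread(path)
    if arr.ndim == 3:
        if arr.shape[2] >= 3:
            arr = arr[..., :3].astype(np.float64) @ _LUMA
        else:  # single channel stored with a trailing axis
            arr = arr[..., 0]
    elif arr.ndim != 2:
        raise ValueError(f"unsupported image dimensionality: shape {arr.shape}")
    return as_gray_image(arr)


def write_gray(image, path: str | os.PathLike, bit_depth: int = 8, clamp: bool = False) -> None:
    """Write a gray image as 8- or 16-bit PNG/TIFF.

    Values are rounded to the nearest integer; values outside the
    representable range raise unless ``clamp`` is set.
    """
    img = as_gray_image(image)
    if bit_depth not in (8, 16):
        raise ValueError(f"bit_depth must be 8 or 16, got {bit_depth}")
    vmax = 2**bit_depth - 1
    rounded = np.rint(img)
    if clamp:
        rounded = np.clip(rounded, 0, vmax)
    elif img.min() < 0 or img.max() > vmax:
        raise ValueError(
            f"values outside [0, {vmax}] after rounding "
            f"(range [{img.min():g}, {img.max():g}]); normalize first or pass clamp=True"
        )
    dtype = np.uint8 if bit_depth == 8 else np.uint16
    iio.imwrite(os.fspath(path), rounded.astype(dtype))


def median_filter(image, radius: int = 1) -> np.ndarray:
    """Square-window median filter, y(m,n) = median over the (2r+1)^2 neighborhood.

    The window includes the center pixel; borders are handled by edge
    replication so the output has the input's shape.
    """
    img = as_gray_image(image)
    if radius < 1:
        raise ValueError(f"radius must be >= 1, got {radius}")
    if radius >= min(img.shape) / 2:
        raise ValueError(f"radius {radius} too large for shape {img.shape}")
    return ndi.median_filter(img, size=2 * radius + 1, mode="nearest")


def normalize(image, spec: NormSpec = NormSpec()) -> np.ndarray:
    """Min-max rescale: I* = a_new + (b_new - a_new)(I - a)/(b - a).

    ``a`` and ``b`` are the input min and max; a constant image is rejected.
    """
    img = as_gray_image(image)
    a, b = img.min(), img.max()
    if b == a:
        raise ValueError("cannot normalize a constant image (max == min)")
    return spec.a_new + (spec.b_new - spec.a_new) * (img - a) / (b - a)


def add_gaussian_noise(image, noise: NoiseSpec) -> np.ndarray:
    """Return image + i.i.d. N(0, sigma^2) draws; deterministic given the seed.

    No clipping is applied -- noisy values may leave the input range.
    """
    img = as_gray_image(image)
    if noise.sigma == 0:
        return img.copy()
    rng = np.random.default_rng(noise.seed)
    return img + rng.normal(0.0, noise.sigma, size=img.shape)


def psnr(reference, estimate, peak: float = 255.0) -> float:
    """Peak signal-to-noise ratio 10*log10(peak^2 / MSE) in decibels.

    Identical images have zero MSE and no finite PSNR; that case raises.
    """
    ref = as_gray_image(reference)
    est = as_gray_image(estimate)
    if ref.shape != est.shape:
        raise ValueError(f"shape mismatch: {ref.shape} vs {est.shape}")
    if np.array_equal(ref, est):
        raise ValueError("PSNR is undefined for identical images (zero MSE)")
    return float(peak_signal_noise_ratio(ref, est, data_range=peak))
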