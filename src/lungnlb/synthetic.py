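"""Synthetic lung-nodule phantoms with ground-truth masks and labels.

Each phantom is a smooth lung-field background carrying one nodule: benign
nodules are disks with a soft Gaussian intensity profile, malignant nodules
are star-shaped regions whose boundary radius is cosine-modulated,
r(theta) = R (1 + A cos(k theta)) -- a simple analytic model of spiculation
with known ground truth for the radial-signature features.  Additive white
Gaussian noise of chosen sigma corrupts the clean image.  Everything is
deterministic given the seed.

The default dataset composition mirrors a 6782 benign / 8218 malignant
clinical collection (malignant fraction 8218/15000 ~ 0.548).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.ndimage as ndi

from .classifier import BENIGN, MALIGNANT
from .imageprep import NoiseSpec, add_gaussian_noise

__all__ = ["PhantomSpec", "Phantom", "make_phantom", "draw_spec", "make_dataset",
           "DEFAULT_MALIGNANT_FRACTION"]

DEFAULT_MALIGNANT_FRACTION = 8218 / 15000

_BG_LO, _BG_HI = 40.0, 80.0


@dataclass(frozen=True)
class PhantomSpec:
    """Fully resolved parameters of one phantom image."""

    size: int = 128
    class_label: str = BENIGN
    nodule_radius: float = 10.0
    spike_count: int | None = None
    spike_amplitude: float | None = None
    contrast: float = 60.0
    background_smoothness: float = 8.0
    sigma: float = 20.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.nodule_radius < 4:
            raise ValueError(f"nodule_radius must be >= 4, got {self.nodule_radius}")
        if self.contrast <= 0:
            raise ValueError("contrast must be > 0")
        malignant = self.class_label == MALIGNANT
        if malignant != (self.spike_count is not None) or malignant != (
            self.spike_amplitude is not None
        ):
            raise ValueError("spike parameters must be present iff the class is malignant")
        amp = self.spike_amplitude or 0.0
        if self.nodule_radius * (1 + amp) >= self.size / 2 - 2:
            raise ValueError("nodule (with spikes) exceeds the image bounds")


@dataclass(frozen=True)
class Phantom:
    clean: np.ndarray
    noisy: np.ndarray
    mask: np.ndarray
    label: str
    spec: PhantomSpec


def _background(size: int, smoothness: float, rng: np.random.Generator) -> np.ndarray:
    field = rng.standard_normal((size, size))
    field = ndi.gaussian_filter(field, smoothness, mode="reflect")
    lo, hi = field.min(), field.max()
    if hi == lo:  # pathological smoothness; fall back to mid-gray
        return np.full((size, size), (_BG_LO + _BG_HI) / 2)
    return _BG_LO + (_BG_HI - _BG_LO) * (field - lo) / (hi - lo)


def make_phantom(spec: PhantomSpec) -> Phantom:
    """Render one phantom: clean image, noisy image, exact nodule mask, label."""
    rng = np.random.default_rng(spec.seed)
    clean = _background(spec.size, spec.background_smoothness, rng)

    # nodule center jittered around the image center, kept fully inside
    amp = spec.spike_amplitude or 0.0
    reach = spec.nodule_radius * (1 + amp)
    max_jitter = max(0.0, min(spec.size / 8, spec.size / 2 - reach - 2))
    cy, cx = spec.size / 2 + rng.uniform(-max_jitter, max_jitter, size=2)

    yy, xx = np.mgrid[0 : spec.size, 0 : spec.size]
    dy, dx = yy - cy, xx - cx
    dist = np.hypot(dy, dx)
    if spec.class_label == MALIGNANT:
        theta = np.arctan2(dy, dx)
        r_theta = spec.nodule_radius * (1 + amp * np.cos(spec.spike_count * theta))
    else:
        r_theta = np.full_like(dist, spec.nodule_radius)
    mask = dist <= r_theta
    # soft Gaussian intensity profile peaking at +contrast, ~0 at the boundary
    profile = np.exp(-0.5 * (dist / (r_theta / 2.5)) ** 2)
    clean = clean + spec.contrast * np.where(mask, profile, 0.0)

    noisy = add_gaussian_noise(clean, NoiseSpec(sigma=spec.sigma, seed=spec.seed + 1))
    return Phantom(clean=clean, noisy=noisy, mask=mask, label=spec.class_label, spec=spec)


def draw_spec(
    class_label: str,
    seed: int,
    size: int = 128,
    sigma: float = 20.0,
    contrast: float = 60.0,
    background_smoothness: float = 8.0,
) -> PhantomSpec:
    """Draw per-nodule morphology parameters from their stated distributions.

    Radius ~ U(6, 14); malignant nodules additionally draw an integer spike
    count U{5..12} and a spike amplitude U(0.3, 0.7) (fraction of radius).
    """
    rng = np.random.default_rng(seed)
    radius = rng.uniform(6.0, 14.0)
    if class_label == MALIGNANT:
        spikes = int(rng.integers(5, 13))
        amplitude = float(rng.uniform(0.3, 0.7))
    else:
        spikes = amplitude = None
    return PhantomSpec(
        size=size,
        class_label=class_label,
        nodule_radius=float(radius),
        spike_count=spikes,
        spike_amplitude=amplitude,
        contrast=contrast,
        background_smoothness=background_smoothness,
        sigma=sigma,
        seed=seed,
    )


def make_dataset(
    n: int,
    malignant_fraction: float = DEFAULT_MALIGNANT_FRACTION,
    sigma: float = 20.0,
    seed: int = 0,
    size: int = 128,
) -> list[Phantom]:
    """Generate a deterministically shuffled labeled phantom collection.

    round(n * malignant_fraction) phantoms are malignant, the rest benign;
    per-sample seeds derive from the master seed.
    """
    if n < 4:
        raise ValueError(f"need n >= 4, got {n}")
    if not 0 < malignant_fraction < 1:
        raise ValueError(f"malignant_fraction must be in (0, 1), got {malignant_fraction}")
    n_mal = int(round(n * malignant_fraction))
    labels = [MALIGNANT] * n_mal + [BENIGN] * (n - n_mal)
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    sample_seeds = rng.integers(0, 2**31 - 1, size=n)
    return [
        make_phantom(draw_spec(labels[i], int(sample_seeds[i]), size=size, sigma=sigma))
        for i in order
    ]
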