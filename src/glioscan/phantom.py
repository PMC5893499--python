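"""Synthetic brain-like phantoms with ground-truth tumor masks.

Clinical MRI data cannot ship with the package, so every pipeline stage
is exercised on generated phantoms: an elliptical "brain" of textured
tissue on a dark background, optionally containing a brighter elliptical
"tumor", corrupted by additive Gaussian noise and salt-and-pepper
impulses. Ground truth (the exact tumor ellipse and the normal/abnormal
label) is known by construction, independent of whether segmentation
succeeds.

The background texture is Gaussian white noise blurred to a chosen
correlation length and rescaled — simple, seedable, and enough to give
non-degenerate co-occurrence statistics (a flat background would produce
the trivial single-cell GLCM). The phantoms make no attempt at
anatomical realism: no skull, CSF or tissue classes, and no MRI physics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from scipy import ndimage

from .imaging_io import GrayImage

__all__ = ["PhantomSpec", "generate_phantom", "generate_dataset", "DEFAULT_JITTER"]


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of one phantom image.

    Defaults describe a 256×256 scan-like image: a (100, 80) px brain
    ellipse at mean intensity 120 with texture of correlation length 4 px
    and amplitude 10 gray levels, a (20, 15) px tumor at +80 gray levels
    (well above the +50 contrast the segmentation stage assumes), noise
    SD 5 and 1% impulse pixels.
    """

    size: tuple[int, int] = (256, 256)
    brain_axes: tuple[float, float] = (100.0, 80.0)
    brain_intensity: float = 120.0
    texture_scale: float = 4.0
    texture_amplitude: float = 10.0
    tumor_present: bool = True
    tumor_center: tuple[float, float] = (128.0, 128.0)
    tumor_axes: tuple[float, float] = (20.0, 15.0)
    tumor_intensity_offset: float = 80.0
    noise_sigma: float = 5.0
    impulse_fraction: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.impulse_fraction <= 0.1:
            raise ValueError("impulse_fraction must lie in [0, 0.1]")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be non-negative")
        if min(self.size) < 2:
            raise ValueError("phantom size must be at least 2x2")


def _ellipse_mask(
    shape: tuple[int, int], center: tuple[float, float], axes: tuple[float, float]
) -> np.ndarray:
    rr, cc = np.ogrid[: shape[0], : shape[1]]
    a, b = axes
    return ((rr - center[0]) / a) ** 2 + ((cc - center[1]) / b) ** 2 <= 1.0


def generate_phantom(spec: PhantomSpec) -> tuple[GrayImage, np.ndarray, str]:
    """Render one phantom; returns (image, tumor mask, label).

    Deterministic given ``spec.seed``. The mask is the exact tumor
    ellipse (all false when no tumor), and the label is ``"abnormal"``
    exactly when a tumor is present. Raises when the tumor ellipse is not
    fully inside the brain ellipse.
    """
    rng = np.random.default_rng(spec.seed)
    shape = spec.size
    brain_center = ((shape[0] - 1) / 2.0, (shape[1] - 1) / 2.0)
    brain = _ellipse_mask(shape, brain_center, spec.brain_axes)

    if spec.tumor_present:
        tumor = _ellipse_mask(shape, spec.tumor_center, spec.tumor_axes)
        if np.any(tumor & ~brain):
            raise ValueError("tumor ellipse extends outside the brain ellipse")
    else:
        tumor = np.zeros(shape, dtype=bool)

    img = np.zeros(shape, dtype=np.float64)
    if (
        spec.texture_amplitude > 0
        and spec.texture_scale > 0
        and math.isfinite(spec.texture_scale)
    ):
        field = ndimage.gaussian_filter(rng.standard_normal(shape), spec.texture_scale)
        sd = field.std()
        if sd > 0:
            field = field / sd * spec.texture_amplitude
        img[brain] = spec.brain_intensity + field[brain]
    else:  # infinite correlation length: flat tissue
        img[brain] = spec.brain_intensity
    # the tumor renders as a homogeneous enhancing mass: the offset
    # replaces the local texture so intra-tumor variability is set by
    # noise_sigma alone, matching the contrast the segmenter assumes
    img[tumor] = spec.brain_intensity + spec.tumor_intensity_offset

    if spec.noise_sigma > 0:
        img += rng.normal(0.0, spec.noise_sigma, size=shape)
    if spec.impulse_fraction > 0:
        n_impulse = int(round(spec.impulse_fraction * img.size))
        if n_impulse > 0:
            flat = rng.choice(img.size, size=n_impulse, replace=False)
            vals = rng.choice([0.0, 255.0], size=n_impulse)
            img.ravel()[flat] = vals

    pixels = np.clip(np.rint(img), 0, 255).astype(np.uint8)
    label = "abnormal" if spec.tumor_present else "normal"
    return GrayImage(pixels, bit_depth=8), tumor, label


#: per-item jitter applied by generate_dataset: tumor center within
#: ±center px of the base center, semi-axes and intensity offset uniform
#: over the given ranges
DEFAULT_JITTER: dict = {
    "center": 12.0,
    "axes": (12.0, 26.0),
    "offset": (60.0, 100.0),
}


def generate_dataset(
    n_normal: int,
    n_abnormal: int,
    base_spec: PhantomSpec | None = None,
    jitter: dict | None = None,
    seed: int = 0,
) -> list[tuple[GrayImage, np.ndarray, str]]:
    """Generate a labeled phantom cohort (normals first, then abnormals).

    Tumor position, semi-axes and contrast are jittered per item with a
    seeded RNG, so two calls with identical arguments return identical
    images and label sequences. Jitter ranges that push a tumor outside
    the brain raise a validation error.
    """
    if n_normal < 0 or n_abnormal < 0:
        raise ValueError("counts must be non-negative")
    base = base_spec if base_spec is not None else PhantomSpec()
    jit = dict(DEFAULT_JITTER if jitter is None else jitter)
    rng = np.random.default_rng(seed)

    items: list[tuple[GrayImage, np.ndarray, str]] = []
    for _ in range(n_normal):
        spec = replace(
            base,
            tumor_present=False,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        items.append(generate_phantom(spec))
    for _ in range(n_abnormal):
        dc = jit.get("center", 0.0)
        center = (
            base.tumor_center[0] + rng.uniform(-dc, dc),
            base.tumor_center[1] + rng.uniform(-dc, dc),
        )
        ax_lo, ax_hi = jit.get("axes", (base.tumor_axes[0], base.tumor_axes[0]))
        axes = (rng.uniform(ax_lo, ax_hi), rng.uniform(ax_lo, ax_hi))
        off_lo, off_hi = jit.get(
            "offset", (base.tumor_intensity_offset, base.tumor_intensity_offset)
        )
        spec = replace(
            base,
            tumor_present=True,
            tumor_center=center,
            tumor_axes=axes,
            tumor_intensity_offset=rng.uniform(off_lo, off_hi),
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        try:
            items.append(generate_phantom(spec))
        except ValueError as exc:
            raise ValueError(f"jitter produced an invalid phantom: {exc}") from exc
    return items
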