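"""Multi-level 2D discrete wavelet decomposition.

Each level splits the current approximation into four subbands by
separable row/column filtering with an orthonormal low/high-pass pair
followed by dyadic downsampling: LL (approximation), LH (horizontal
detail), HL (vertical detail) and HH (diagonal detail). Level 1 is
computed from the input image; level k from level k-1's LL. The LL and
HL subbands are the texture-analysis inputs downstream.

Filtering and reconstruction are delegated to PyWavelets; subband naming
follows the detail-direction convention (LH = horizontal edges, HL =
vertical edges), i.e. LL/LH/HL/HH map onto pywt's cA/cH/cV/cD.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pywt

from .imaging_io import GrayImage

__all__ = [
    "SubbandLevel",
    "WaveletDecomposition",
    "decompose",
    "reconstruct",
    "select_subbands",
]

BANDS = ("LL", "LH", "HL", "HH")


@dataclass(frozen=True)
class SubbandLevel:
    """The four coefficient arrays of one decomposition level."""

    LL: np.ndarray
    LH: np.ndarray
    HL: np.ndarray
    HH: np.ndarray
    input_shape: tuple[int, int]  # shape of the array this level decomposed

    def band(self, name: str) -> np.ndarray:
        if name not in BANDS:
            raise ValueError(f"unknown subband {name!r}")
        return getattr(self, name)


@dataclass(frozen=True)
class WaveletDecomposition:
    """Multi-level pyramid of wavelet subbands, levels indexed from 1."""

    levels: tuple[SubbandLevel, ...]
    wavelet_name: str
    boundary_mode: str

    @property
    def n_levels(self) -> int:
        return len(self.levels)

    def level(self, k: int) -> SubbandLevel:
        if not 1 <= k <= self.n_levels:
            raise ValueError(
                f"level {k} not in decomposition (has {self.n_levels} levels)"
            )
        return self.levels[k - 1]


def _feasible_depth(
    shape: tuple[int, int], wavelet: pywt.Wavelet, mode: str, requested: int
) -> int:
    """Levels (capped at ``requested``) whose input keeps both dims >= 2.

    Longer filters have a fixed-point coefficient length, so the shape
    sequence need not shrink forever; the cap keeps this finite.
    """
    depth = 0
    rows, cols = shape
    while depth < requested and min(rows, cols) >= 2:
        rows = pywt.dwt_coeff_len(rows, wavelet.dec_len, mode)
        cols = pywt.dwt_coeff_len(cols, wavelet.dec_len, mode)
        depth += 1
    return depth


def decompose(
    img: GrayImage | np.ndarray,
    wavelet_name: str = "haar",
    n_levels: int = 4,
    boundary_mode: str = "symmetric",
) -> WaveletDecomposition:
    """Run an ``n_levels``-deep 2D DWT on a grayscale image.

    Raises a ``ValueError`` naming the deepest feasible level when the
    image is too small for the requested depth (every level must keep
    both dimensions >= 2 before being decomposed).
    """
    arr = img.pixels if isinstance(img, GrayImage) else np.asarray(img)
    arr = arr.astype(np.float64)
    if arr.ndim != 2:
        raise ValueError("decompose expects a 2D array")
    if n_levels < 1:
        raise ValueError("n_levels must be >= 1")
    wavelet = pywt.Wavelet(wavelet_name)
    feasible = _feasible_depth(arr.shape, wavelet, boundary_mode, n_levels)
    if n_levels > feasible:
        raise ValueError(
            f"image of shape {arr.shape} supports at most {feasible} "
            f"decomposition level(s) with {wavelet_name!r}; {n_levels} requested"
        )

    levels = []
    current = arr
    for _ in range(n_levels):
        (ll, (lh, hl, hh)) = pywt.dwt2(current, wavelet, mode=boundary_mode)
        levels.append(
            SubbandLevel(LL=ll, LH=lh, HL=hl, HH=hh, input_shape=current.shape)
        )
        current = ll
    return WaveletDecomposition(
        levels=tuple(levels), wavelet_name=wavelet_name, boundary_mode=boundary_mode
    )


def reconstruct(dec: WaveletDecomposition) -> np.ndarray:
    """Invert the decomposition level by level (perfect reconstruction).

    For orthonormal filters the result matches the original image to
    floating-point precision.
    """
    wavelet = pywt.Wavelet(dec.wavelet_name)
    current = dec.levels[-1].LL
    for lvl in reversed(dec.levels):
        current = pywt.idwt2(
            (current, (lvl.LH, lvl.HL, lvl.HH)), wavelet, mode=dec.boundary_mode
        )
        # idwt2 may overshoot by one row/col when the decomposed array was odd
        current = current[: lvl.input_shape[0], : lvl.input_shape[1]]
    return current


def select_subbands(
    dec: WaveletDecomposition,
    levels: Sequence[int],
    bands: Sequence[str] = ("LL", "HL"),
) -> list[tuple[int, str, np.ndarray]]:
    """Project out (level, band) subbands in a deterministic order.

    Ordering is by level ascending with LL before HL, regardless of the
    order of the ``levels``/``bands`` arguments.
    """
    for b in bands:
        if b not in ("LL", "HL"):
            raise ValueError(f"band must be 'LL' or 'HL', got {b!r}")
    for k in levels:
        if not 1 <= k <= dec.n_levels:
            raise ValueError(
                f"level {k} not in decomposition (has {dec.n_levels} levels)"
            )
    band_order = [b for b in ("LL", "HL") if b in set(bands)]
    out = []
    for k in sorted(set(int(k) for k in levels)):
        for b in band_order:
            out.append((k, b, dec.level(k).band(b)))
    return out
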