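"""Image reading/writing, grayscale conversion, denoising and fidelity metrics.

All pipeline stages operate on :class:`GrayImage`, a 2D array of
non-negative integers with a declared bit depth ``m`` (pixel values in
``[0, 2**m - 1]``). Sources deeper than 8 bits are min–max rescaled to
8 bits on load so that co-occurrence quantization and the PSNR peak
``2**m - 1`` use ``m = 8`` uniformly.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from PIL import Image
from scipy import ndimage

__all__ = [
    "GrayImage",
    "QualityReport",
    "load_image",
    "save_image",
    "save_mask",
    "denoise",
    "mse",
    "psnr",
    "write_quality_csv",
]

#: luminance weights used to collapse RGB inputs to a single channel
_LUMA = np.array([0.299, 0.587, 0.114])


@dataclass(frozen=True)
class GrayImage:
    """A 2D grayscale image with an explicit bit depth.

    Parameters
    ----------
    pixels
        2D array of non-negative integers, row-major, 0-based (row, col).
    bit_depth
        Bits per pixel ``m``; all values must lie in ``[0, 2**m - 1]``.
    """

    pixels: np.ndarray
    bit_depth: int = 8

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 2:
            raise ValueError(f"GrayImage requires a 2D array, got ndim={px.ndim}")
        if px.shape[0] < 2 or px.shape[1] < 2:
            raise ValueError(f"GrayImage dimensions must be >= 2, got {px.shape}")
        if not np.issubdtype(px.dtype, np.integer):
            raise ValueError(f"GrayImage pixels must be integers, got {px.dtype}")
        peak = 2**self.bit_depth - 1
        if px.min() < 0 or px.max() > peak:
            raise ValueError(
                f"pixel values outside [0, {peak}] for bit_depth={self.bit_depth}"
            )
        object.__setattr__(self, "pixels", px)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    @property
    def peak(self) -> int:
        """Maximum representable intensity, ``2**m - 1``."""
        return 2**self.bit_depth - 1


@dataclass(frozen=True)
class QualityReport:
    """Fidelity metrics and pixel areas for one processed image."""

    mse: float
    psnr_db: float
    area_image_px: int
    area_region_px: int

    def __post_init__(self) -> None:
        if self.mse < 0:
            raise ValueError("mse must be non-negative")
        if (self.mse == 0) != math.isinf(self.psnr_db):
            raise ValueError("psnr must be +inf exactly when mse == 0")
        if not 0 <= self.area_region_px <= self.area_image_px:
            raise ValueError("region area must lie in [0, image area]")


def _to_8bit(arr: np.ndarray) -> np.ndarray:
    """Min–max rescale an intensity array to [0, 255]; constant maps to 0."""
    arr = np.asarray(arr, dtype=np.float64)
    lo, hi = arr.min(), arr.max()
    if hi == lo:
        return np.zeros(arr.shape, dtype=np.uint8)
    return np.rint(255.0 * (arr - lo) / (hi - lo)).astype(np.uint8)


def _infer_dialect(path: Path) -> str:
    suffix = path.suffix.lower()
    if suffix in {".dcm", ".dicom"}:
        return "dicom"
    if suffix == ".png":
        return "png"
    if suffix in {".tif", ".tiff"}:
        return "tiff"
    raise ValueError(f"cannot infer image dialect from suffix {suffix!r}")


def _read_dicom(path: Path) -> np.ndarray:
    import pydicom

    ds = pydicom.dcmread(str(path))
    n_frames = int(getattr(ds, "NumberOfFrames", 1))
    if n_frames != 1:
        raise ValueError(
            f"multi-frame DICOM ({n_frames} frames) not supported; "
            "extract a single 2D frame first"
        )
    arr = ds.pixel_array
    if arr.ndim == 3 and arr.shape[-1] in (3, 4):  # color DICOM
        arr = np.rint(arr[..., :3] @ _LUMA).astype(np.int64)
    return np.asarray(arr)


def _read_raster(path: Path) -> np.ndarray:
    with Image.open(path) as im:
        arr = np.asarray(im)
    if arr.ndim == 3:
        arr = np.rint(arr[..., :3] @ _LUMA).astype(np.int64)
    return arr


def load_image(path: str | Path, dialect: str | None = None) -> GrayImage:
    """Load a 2D image as an 8-bit :class:`GrayImage`.

    Color inputs are converted to luminance (weights 0.299/0.587/0.114);
    sources deeper than 8 bits are min–max rescaled into [0, 255]. Only
    single-frame DICOM files are accepted.

    Parameters
    ----------
    path
        Image file path.
    dialect
        One of ``{"dicom", "png", "tiff"}``; inferred from the file suffix
        when omitted.
    """
    path = Path(path)
    if dialect is None:
        dialect = _infer_dialect(path)
    if dialect not in {"dicom", "png", "tiff"}:
        raise ValueError(f"unknown dialect {dialect!r}")
    try:
        if dialect == "dicom":
            arr = _read_dicom(path)
        else:
            arr = _read_raster(path)
    except (OSError, Exception) as exc:  # noqa: BLE001 - re-raise with dialect
        if isinstance(exc, ValueError):
            raise
        raise OSError(f"cannot read {path} as {dialect}: {exc}") from exc
    arr = np.asarray(arr)
    if arr.ndim != 2:
        raise ValueError(f"expected a 2D grayscale image, got shape {arr.shape}")
    if arr.size == 0 or min(arr.shape) < 2:
        raise ValueError(f"degenerate image shape {arr.shape}")
    if np.issubdtype(arr.dtype, np.integer) and arr.min() >= 0 and arr.max() <= 255:
        return GrayImage(arr.astype(np.uint8), bit_depth=8)
    return GrayImage(_to_8bit(arr), bit_depth=8)


def save_image(img: GrayImage, path: str | Path) -> None:
    """Write an 8-bit grayscale PNG (bit-exact round trip with load_image)."""
    if img.bit_depth != 8:
        raise ValueError("only 8-bit images can be written as PNG")
    Image.fromarray(img.pixels.astype(np.uint8), mode="L").save(Path(path))


def save_mask(mask: np.ndarray, path: str | Path) -> None:
    """Write a binary mask as an 8-bit PNG with values {0, 255}."""
    arr = np.where(np.asarray(mask, dtype=bool), 255, 0).astype(np.uint8)
    Image.fromarray(arr, mode="L").save(Path(path))


def denoise(img: GrayImage, method: str = "median", window: int = 3) -> GrayImage:
    """Remove impulse noise with a square median filter.

    ``method="none"`` returns the input unchanged. Borders are handled by
    edge replication, so output shape and bit depth match the input.
    """
    if method == "none":
        return img
    if method != "median":
        raise ValueError(f"unknown denoise method {method!r}")
    if window < 1 or window % 2 == 0:
        raise ValueError(f"median window must be odd and >= 1, got {window}")
    out = ndimage.median_filter(img.pixels, size=window, mode="nearest")
    return GrayImage(out, bit_depth=img.bit_depth)


def _check_shapes(original: GrayImage, processed: GrayImage) -> None:
    if original.shape != processed.shape:
        raise ValueError(
            f"shape mismatch: {original.shape} vs {processed.shape}"
        )


def mse(original: GrayImage, processed: GrayImage) -> float:
    """Mean squared error ``(1/(P*Q)) * sum (f - f_R)**2`` between two images."""
    _check_shapes(original, processed)
    diff = original.pixels.astype(np.int64) - processed.pixels.astype(np.int64)
    return float(np.mean(diff.astype(np.float64) ** 2))


def psnr(
    original: GrayImage,
    processed: GrayImage,
    formula: str = "as_printed",
) -> float:
    """Peak signal-to-noise ratio in decibels.

    Two variants are provided. ``as_printed`` evaluates
    ``20*log10((2**m - 1)/MSE)``; ``standard`` uses the conventional
    ``20*log10((2**m - 1)/sqrt(MSE))``. Identical images return ``+inf``.
    """
    _check_shapes(original, processed)
    if original.bit_depth != processed.bit_depth:
        raise ValueError("bit depths differ; PSNR peak is ambiguous")
    if formula not in {"as_printed", "standard"}:
        raise ValueError(f"unknown psnr formula {formula!r}")
    err = mse(original, processed)
    if err == 0:
        return math.inf
    peak = float(original.peak)
    denom = err if formula == "as_printed" else math.sqrt(err)
    return 20.0 * math.log10(peak / denom)


def write_quality_csv(
    rows: Iterable[tuple[str, QualityReport]], path: str | Path
) -> None:
    """Serialize quality reports as CSV.

    Header is ``image,psnr,mse,area_image_px,area_tumor_px``.
    """
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["image", "psnr", "mse", "area_image_px", "area_tumor_px"])
        for name, rep in rows:
            writer.writerow(
                [
                    name,
                    "inf" if math.isinf(rep.psnr_db) else f"{rep.psnr_db:.6g}",
                    f"{rep.mse:.6g}",
                    rep.area_image_px,
                    rep.area_region_px,
                ]
            )
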