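"""Seeded region growing and binary morphology for tumor isolation.

The region grows outward from seed pixels, absorbing a neighbor exactly
when its intensity lies within ``delta`` of the region's mean at the
moment the pixel is examined. The frontier is a FIFO queue with a fixed
neighbor push order (up, left, right, down, then the four diagonals), so
results are fully deterministic even in running-mean mode, where the
acceptance threshold drifts as the region grows.

Morphological cleanup (opening followed by small-component removal and
largest-component selection) strips segmentation speckle before the
region's pixel area is reported.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import ndimage

from .imaging_io import GrayImage

__all__ = [
    "SeedSet",
    "RegionGrowParams",
    "StructuringElement",
    "square_se",
    "cross_se",
    "grow_region",
    "dilate",
    "erode",
    "clean_mask",
    "region_area",
    "auto_seed",
]

# neighbor probe order: up, left, right, down, then diagonals
# (up-left, up-right, down-left, down-right) for 8-connectivity
_NEIGHBORS_4 = ((-1, 0), (0, -1), (0, 1), (1, 0))
_NEIGHBORS_8 = _NEIGHBORS_4 + ((-1, -1), (-1, 1), (1, -1), (1, 1))


@dataclass(frozen=True)
class SeedSet:
    """Ordered list of 0-based (row, col) seed coordinates."""

    points: tuple[tuple[int, int], ...]

    def __init__(self, points: Sequence[tuple[int, int]]):
        if len(points) == 0:
            raise ValueError("SeedSet must contain at least one point")
        object.__setattr__(
            self, "points", tuple((int(r), int(c)) for r, c in points)
        )

    def validate_for(self, shape: tuple[int, int]) -> None:
        for r, c in self.points:
            if not (0 <= r < shape[0] and 0 <= c < shape[1]):
                raise ValueError(f"seed ({r}, {c}) outside image bounds {shape}")


@dataclass(frozen=True)
class RegionGrowParams:
    """Region-growing controls.

    ``delta`` is the intensity tolerance (8-bit gray levels) around the
    region mean; ``mean_mode="running"`` updates the mean after every
    accepted pixel, ``"fixed"`` freezes it at the seed-set mean.
    """

    delta: float = 10.0
    connectivity: int = 4
    mean_mode: str = "running"

    def __post_init__(self) -> None:
        if self.delta < 0:
            raise ValueError("delta must be non-negative")
        if self.connectivity not in (4, 8):
            raise ValueError("connectivity must be 4 or 8")
        if self.mean_mode not in ("running", "fixed"):
            raise ValueError("mean_mode must be 'running' or 'fixed'")


@dataclass(frozen=True)
class StructuringElement:
    """Small binary footprint with an origin cell inside it."""

    footprint: np.ndarray
    origin: tuple[int, int]

    def __post_init__(self) -> None:
        fp = np.asarray(self.footprint, dtype=bool)
        if fp.ndim != 2 or not fp.any():
            raise ValueError("footprint must be a non-empty 2D boolean array")
        r, c = self.origin
        if not (0 <= r < fp.shape[0] and 0 <= c < fp.shape[1]):
            raise ValueError("origin outside footprint")
        if not fp[r, c]:
            raise ValueError("origin cell of the footprint must be true")
        object.__setattr__(self, "footprint", fp)
        object.__setattr__(self, "origin", (int(r), int(c)))

    def offsets(self) -> list[tuple[int, int]]:
        """Offsets of true cells relative to the origin."""
        rr, cc = np.nonzero(self.footprint)
        return [(int(r - self.origin[0]), int(c - self.origin[1])) for r, c in zip(rr, cc)]


def square_se(size: int = 3) -> StructuringElement:
    """Square footprint with centered origin (the default element)."""
    if size < 1 or size % 2 == 0:
        raise ValueError("square structuring element size must be odd")
    fp = np.ones((size, size), dtype=bool)
    return StructuringElement(fp, (size // 2, size // 2))


def cross_se(size: int = 3) -> StructuringElement:
    """Plus-shaped footprint with centered origin."""
    if size < 1 or size % 2 == 0:
        raise ValueError("cross structuring element size must be odd")
    fp = np.zeros((size, size), dtype=bool)
    fp[size // 2, :] = True
    fp[:, size // 2] = True
    return StructuringElement(fp, (size // 2, size // 2))


def grow_region(
    img: GrayImage,
    seeds: SeedSet | Sequence[tuple[int, int]],
    params: RegionGrowParams = RegionGrowParams(),
) -> np.ndarray:
    """Grow a connected region from seed pixels by intensity similarity.

    Seeds are always part of the region. A frontier pixel joins exactly
    when ``|intensity - region_mean| <= delta`` at the moment it is popped
    from the FIFO queue; each pixel is examined at most once.

    Returns a boolean mask of the image shape.
    """
    if not isinstance(seeds, SeedSet):
        seeds = SeedSet(seeds)
    seeds.validate_for(img.shape)

    neighbors = _NEIGHBORS_4 if params.connectivity == 4 else _NEIGHBORS_8
    vals = img.pixels.astype(np.float64)
    n_rows, n_cols = img.shape

    mask = np.zeros(img.shape, dtype=bool)
    enqueued = np.zeros(img.shape, dtype=bool)
    queue: deque[tuple[int, int]] = deque()

    region_sum = 0.0
    region_n = 0
    for r, c in seeds.points:
        if mask[r, c]:
            continue
        mask[r, c] = True
        enqueued[r, c] = True
        region_sum += vals[r, c]
        region_n += 1
    mean = region_sum / region_n
    frozen_mean = mean  # seed-set mean, used when mean_mode == "fixed"

    for r, c in seeds.points:
        for dr, dc in neighbors:
            nr, nc = r + dr, c + dc
            if 0 <= nr < n_rows and 0 <= nc < n_cols and not enqueued[nr, nc]:
                enqueued[nr, nc] = True
                queue.append((nr, nc))

    while queue:
        r, c = queue.popleft()
        ref = mean if params.mean_mode == "running" else frozen_mean
        if abs(vals[r, c] - ref) > params.delta:
            continue
        mask[r, c] = True
        if params.mean_mode == "running":
            region_sum += vals[r, c]
            region_n += 1
            mean = region_sum / region_n
        for dr, dc in neighbors:
            nr, nc = r + dr, c + dc
            if 0 <= nr < n_rows and 0 <= nc < n_cols and not enqueued[nr, nc]:
                enqueued[nr, nc] = True
                queue.append((nr, nc))
    return mask


def _as_bool(mask: np.ndarray) -> np.ndarray:
    mask = np.asarray(mask, dtype=bool)
    if mask.ndim != 2:
        raise ValueError("mask must be 2D")
    return mask


def dilate(mask: np.ndarray, se: StructuringElement) -> np.ndarray:
    """Binary dilation: union of mask translates by the element's offsets.

    Equivalently, an output cell is true iff the reflected footprint placed
    there overlaps a true input cell; pixels outside the image are false.
    """
    mask = _as_bool(mask)
    out = np.zeros_like(mask)
    for dr, dc in se.offsets():
        out |= _shift(mask, dr, dc)
    return out


def erode(mask: np.ndarray, se: StructuringElement) -> np.ndarray:
    """Binary erosion: true where every footprint cell lands on a true cell.

    Pixels outside the image count as false, so a full-true mask erodes to
    its interior.
    """
    mask = _as_bool(mask)
    out = np.ones_like(mask)
    for dr, dc in se.offsets():
        out &= _shift(mask, -dr, -dc)
    return out


def _shift(mask: np.ndarray, dr: int, dc: int) -> np.ndarray:
    """Translate a boolean array by (dr, dc), filling with false."""
    out = np.zeros_like(mask)
    n_rows, n_cols = mask.shape
    src_r = slice(max(0, -dr), min(n_rows, n_rows - dr))
    src_c = slice(max(0, -dc), min(n_cols, n_cols - dc))
    dst_r = slice(max(0, dr), min(n_rows, n_rows + dr))
    dst_c = slice(max(0, dc), min(n_cols, n_cols + dc))
    if src_r.start < src_r.stop and src_c.start < src_c.stop:
        out[dst_r, dst_c] = mask[src_r, src_c]
    return out


def clean_mask(
    mask: np.ndarray,
    se: StructuringElement | None = None,
    min_component_px: int = 25,
) -> np.ndarray:
    """Morphological opening, small-component removal, largest-component pick.

    Opening (erode then dilate with the same element) removes features
    smaller than the element; connected components (8-connectivity) below
    ``min_component_px`` are then dropped and only the largest survivor is
    returned. An all-false result signals that no region was found.
    """
    if min_component_px < 0:
        raise ValueError("min_component_px must be non-negative")
    if se is None:
        se = square_se(3)
    opened = dilate(erode(_as_bool(mask), se), se)
    labels, n = ndimage.label(opened, structure=np.ones((3, 3), dtype=int))
    if n == 0:
        return opened
    sizes = ndimage.sum_labels(opened, labels, index=np.arange(1, n + 1))
    keep = np.nonzero(sizes >= min_component_px)[0]
    if keep.size == 0:
        return np.zeros_like(opened)
    # ties broken by scan order: argmax returns the first (lowest) label
    best = keep[np.argmax(sizes[keep])] + 1
    return labels == best


def region_area(mask: np.ndarray) -> int:
    """Number of true cells in a binary mask."""
    return int(np.count_nonzero(_as_bool(mask)))


def auto_seed(img: GrayImage, bright_fraction: float = 0.01) -> SeedSet:
    """Pick one seed from the brightest pixels of a (denoised) image.

    The seed is the centroid of the brightest ``bright_fraction`` of
    pixels; because the centroid of a non-convex bright set can fall on a
    dark pixel, it is snapped to the nearest bright pixel.
    """
    if not 0 < bright_fraction <= 1:
        raise ValueError("bright_fraction must be in (0, 1]")
    vals = img.pixels
    thresh = np.quantile(vals, 1.0 - bright_fraction)
    rr, cc = np.nonzero(vals >= thresh)
    centroid = np.array([rr.mean(), cc.mean()])
    d2 = (rr - centroid[0]) ** 2 + (cc - centroid[1]) ** 2
    k = int(np.argmin(d2))
    return SeedSet([(int(rr[k]), int(cc[k]))])
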