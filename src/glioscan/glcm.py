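"""Gray-level co-occurrence matrices and Haralick texture features.

A GLCM is the normalized 2D histogram of ordered gray-level pairs
``(reference, neighbor)`` at a fixed pixel offset. The offsets for the
four standard orientations at distance ``S`` are, in (row, col):

====== ==========
angle  offset
====== ==========
0°     (0,  S)
45°    (-S, S)
90°    (-S, 0)
135°   (-S, -S)
====== ==========

With ``symmetric=True`` (the usual Haralick convention, and the default)
each pair is also counted in the reverse direction, making the matrix
symmetric before normalization.

Five scalar texture statistics summarize each matrix, reported in the
fixed order CON, COR, ENE, HOM, ENT:

* contrast      ``sum (p-q)^2 f(p,q)``
* correlation   ``(sum p*q*f(p,q) - mu_p*mu_q) / (sigma_p*sigma_q)``
* energy        ``sqrt(sum f(p,q)^2)``
* homogeneity   ``sum f(p,q) / (1 + (p-q)^2)``
* entropy       ``-sum f(p,q) log2 f(p,q)``

Correlation is undefined when a marginal variance vanishes (e.g. a
constant image); it is then reported as NaN by :func:`correlation` and
mapped to 0 in feature vectors so it cannot poison classifier input.

Wavelet subbands are real-valued, so they are uniformly re-quantized to
``G`` discrete levels before counting (see :func:`quantize`).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "CoocMatrix",
    "FEATURE_ORDER",
    "ANGLE_OFFSETS",
    "quantize",
    "cooc_matrix",
    "contrast",
    "energy",
    "correlation",
    "homogeneity",
    "entropy",
    "glcm_features",
    "feature_vector",
]

FEATURE_ORDER = ("CON", "COR", "ENE", "HOM", "ENT")

#: (row, col) displacement of the neighbor pixel for each orientation, S=1
ANGLE_OFFSETS: Mapping[int, tuple[int, int]] = {
    0: (0, 1),
    45: (-1, 1),
    90: (-1, 0),
    135: (-1, -1),
}


@dataclass(frozen=True)
class CoocMatrix:
    """A normalized G×G co-occurrence matrix plus its raw pair counts."""

    counts: np.ndarray
    probs: np.ndarray
    n_levels: int
    distance: int
    angle: int
    symmetric: bool

    def __post_init__(self) -> None:
        total = self.probs.sum()
        if not math.isclose(total, 1.0, abs_tol=1e-12):
            raise ValueError(f"probabilities sum to {total}, expected 1")
        if self.symmetric and not np.array_equal(self.counts, self.counts.T):
            raise ValueError("symmetric matrix has asymmetric counts")


def quantize(arr: np.ndarray, G: int = 8) -> np.ndarray:
    """Uniformly bin a real array into integer levels ``0..G-1``.

    Bins are equal-width over ``[min, max]``; a constant array maps to
    all zeros.
    """
    if G < 2:
        raise ValueError("G must be >= 2")
    arr = np.asarray(arr, dtype=np.float64)
    lo, hi = arr.min(), arr.max()
    if hi == lo:
        return np.zeros(arr.shape, dtype=np.intp)
    q = np.floor((arr - lo) / (hi - lo) * G).astype(np.intp)
    return np.minimum(q, G - 1)


def cooc_matrix(
    q: np.ndarray,
    S: int = 1,
    angle: int = 0,
    symmetric: bool = True,
    n_levels: int | None = None,
) -> CoocMatrix:
    """Count gray-level pairs at one (distance, angle) and normalize.

    ``q`` must already be quantized to non-negative integers below
    ``n_levels`` (defaults to ``q.max() + 1``). Raises when the offset
    leaves no valid pixel pair (image smaller than the displacement).
    """
    q = np.asarray(q)
    if q.ndim != 2:
        raise ValueError("quantized image must be 2D")
    if not np.issubdtype(q.dtype, np.integer):
        raise ValueError("quantized image must have an integer dtype")
    if angle not in ANGLE_OFFSETS:
        raise ValueError(f"angle must be one of {sorted(ANGLE_OFFSETS)}, got {angle}")
    if S < 1:
        raise ValueError("distance S must be >= 1")
    G = int(q.max()) + 1 if n_levels is None else int(n_levels)
    if q.min() < 0 or q.max() >= G:
        raise ValueError(f"quantized values outside [0, {G - 1}]")

    dr, dc = (d * S for d in ANGLE_OFFSETS[angle])
    n_rows, n_cols = q.shape
    # reference window such that (r + dr, c + dc) stays in bounds
    r0, r1 = max(0, -dr), min(n_rows, n_rows - dr)
    c0, c1 = max(0, -dc), min(n_cols, n_cols - dc)
    if r0 >= r1 or c0 >= c1:
        raise ValueError(
            f"no valid pixel pairs for shape {q.shape} at distance {S}, angle {angle}"
        )
    ref = q[r0:r1, c0:c1].ravel()
    nbr = q[r0 + dr : r1 + dr, c0 + dc : c1 + dc].ravel()
    counts = np.bincount(ref * G + nbr, minlength=G * G).reshape(G, G)
    if symmetric:
        counts = counts + counts.T
    probs = counts / counts.sum()
    return CoocMatrix(
        counts=counts,
        probs=probs,
        n_levels=G,
        distance=S,
        angle=angle,
        symmetric=symmetric,
    )


def _probs(M: CoocMatrix | np.ndarray) -> np.ndarray:
    return M.probs if isinstance(M, CoocMatrix) else np.asarray(M, dtype=np.float64)


def contrast(M: CoocMatrix | np.ndarray) -> float:
    """Intensity contrast between neighbors: ``sum (p-q)^2 f(p,q)``."""
    f = _probs(M)
    p, q = np.indices(f.shape)
    return float(np.sum((p - q) ** 2 * f))


def energy(M: CoocMatrix | np.ndarray) -> float:
    """Amount of pair repetition: ``sqrt(sum f(p,q)^2)`` (root included)."""
    f = _probs(M)
    return float(np.sqrt(np.sum(f**2)))


def correlation(M: CoocMatrix | np.ndarray) -> float:
    """Linear dependence of paired gray levels; NaN when undefined.

    Means and standard deviations come from the row (reference) and
    column (neighbor) marginals; a zero marginal SD makes the statistic
    undefined and returns NaN.
    """
    f = _probs(M)
    G = f.shape[0]
    levels = np.arange(G, dtype=np.float64)
    px = f.sum(axis=1)
    py = f.sum(axis=0)
    mu_p = float(levels @ px)
    mu_q = float(levels @ py)
    sig_p = math.sqrt(float((levels - mu_p) ** 2 @ px))
    sig_q = math.sqrt(float((levels - mu_q) ** 2 @ py))
    if sig_p == 0.0 or sig_q == 0.0:
        return math.nan
    cross = float(np.outer(levels, levels).ravel() @ f.ravel())
    return (cross - mu_p * mu_q) / (sig_p * sig_q)


def homogeneity(M: CoocMatrix | np.ndarray) -> float:
    """Local uniformity: ``sum f(p,q) / (1 + (p-q)^2)``."""
    f = _probs(M)
    p, q = np.indices(f.shape)
    return float(np.sum(f / (1.0 + (p - q) ** 2)))


def entropy(M: CoocMatrix | np.ndarray) -> float:
    """Shannon entropy of the pair distribution in bits; 0*log 0 := 0."""
    f = _probs(M)
    nz = f[f > 0]
    return float(-np.sum(nz * np.log2(nz)))


def glcm_features(M: CoocMatrix | np.ndarray) -> dict[str, float]:
    """All five statistics of one matrix, keyed CON/COR/ENE/HOM/ENT."""
    return {
        "CON": contrast(M),
        "COR": correlation(M),
        "ENE": energy(M),
        "HOM": homogeneity(M),
        "ENT": entropy(M),
    }


def feature_vector(
    subbands: Sequence[tuple[int, str, np.ndarray]],
    G: int = 8,
    S: int = 1,
    angles: Sequence[int] = (0, 45, 90, 135),
    aggregate: str = "mean",
    symmetric: bool = True,
) -> dict[tuple, float]:
    """Texture features over a list of wavelet subbands.

    Each subband is quantized to ``G`` levels, a co-occurrence matrix is
    built per angle, and the five statistics are either averaged over
    angles (``aggregate="mean"``, one value per feature) or kept
    per-angle (``aggregate="per_angle"``, keys gain the angle).

    Keys are ordered by (level ascending, LL before HL, CON/COR/ENE/HOM/ENT);
    an undefined correlation contributes 0 with a logged warning.
    """
    if len(subbands) == 0:
        raise ValueError("subbands must be non-empty")
    if aggregate not in ("mean", "per_angle"):
        raise ValueError("aggregate must be 'mean' or 'per_angle'")
    band_rank = {"LL": 0, "LH": 1, "HL": 2, "HH": 3}
    ordered = sorted(subbands, key=lambda t: (t[0], band_rank.get(t[1], 9)))
    out: dict[tuple, float] = {}
    for level, band, arr in ordered:
        q = quantize(arr, G)
        per_angle: dict[int, dict[str, float]] = {}
        for ang in angles:
            M = cooc_matrix(q, S=S, angle=ang, symmetric=symmetric)
            feats = glcm_features(M)
            if math.isnan(feats["COR"]):
                logger.warning(
                    "correlation undefined (zero marginal variance) for "
                    "level %d band %s angle %d; reporting 0",
                    level,
                    band,
                    ang,
                )
                feats["COR"] = 0.0
            per_angle[ang] = feats
        if aggregate == "mean":
            for name in FEATURE_ORDER:
                out[(level, band, name)] = float(
                    np.mean([per_angle[a][name] for a in angles])
                )
        else:
            for name in FEATURE_ORDER:
                for ang in angles:
                    out[(level, band, name, ang)] = per_angle[ang][name]
    return out
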