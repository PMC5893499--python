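"""Independent brute-force oracles used to check the implementation.

Everything here is deliberately naive — explicit loops over pixels and
pairs — and shares no code with the package.
"""

from __future__ import annotations

import math
from collections import deque

import numpy as np

ANGLE_OFFSETS = {0: (0, 1), 45: (-1, 1), 90: (-1, 0), 135: (-1, -1)}


def bf_glcm_counts(q, S, angle, symmetric):
    """Enumerate every ordered pixel pair at the offset, one by one."""
    q = np.asarray(q)
    G = int(q.max()) + 1
    dr, dc = (d * S for d in ANGLE_OFFSETS[angle])
    counts = np.zeros((G, G), dtype=np.int64)
    rows, cols = q.shape
    for r in range(rows):
        for c in range(cols):
            nr, nc = r + dr, c + dc
            if 0 <= nr < rows and 0 <= nc < cols:
                counts[q[r, c], q[nr, nc]] += 1
                if symmetric:
                    counts[q[nr, nc], q[r, c]] += 1
    return counts


def bf_features(probs):
    """Term-by-term Haralick statistics from a normalized matrix."""
    probs = np.asarray(probs, dtype=float)
    G = probs.shape[0]
    con = sum(
        (p - q) ** 2 * probs[p, q] for p in range(G) for q in range(G)
    )
    ene = math.sqrt(sum(probs[p, q] ** 2 for p in range(G) for q in range(G)))
    hom = sum(
        probs[p, q] / (1 + (p - q) ** 2) for p in range(G) for q in range(G)
    )
    ent = -sum(
        probs[p, q] * math.log2(probs[p, q])
        for p in range(G)
        for q in range(G)
        if probs[p, q] > 0
    )
    px = probs.sum(axis=1)
    py = probs.sum(axis=0)
    mp = sum(p * px[p] for p in range(G))
    mq = sum(q * py[q] for q in range(G))
    sp = math.sqrt(sum((p - mp) ** 2 * px[p] for p in range(G)))
    sq = math.sqrt(sum((q - mq) ** 2 * py[q] for q in range(G)))
    if sp == 0 or sq == 0:
        cor = math.nan
    else:
        cross = sum(p * q * probs[p, q] for p in range(G) for q in range(G))
        cor = (cross - mp * mq) / (sp * sq)
    return {"CON": con, "COR": cor, "ENE": ene, "HOM": hom, "ENT": ent}


def bf_flood_fill(img, seed, delta, connectivity=4):
    """BFS flood fill accepting |v - seed-set mean| <= delta (fixed mean)."""
    img = np.asarray(img, dtype=float)
    rows, cols = img.shape
    mean = img[seed]
    offsets = [(-1, 0), (0, -1), (0, 1), (1, 0)]
    if connectivity == 8:
        offsets += [(-1, -1), (-1, 1), (1, -1), (1, 1)]
    mask = np.zeros(img.shape, dtype=bool)
    mask[seed] = True
    queue = deque([seed])
    while queue:
        r, c = queue.popleft()
        for dr, dc in offsets:
            nr, nc = r + dr, c + dc
            if (
                0 <= nr < rows
                and 0 <= nc < cols
                and not mask[nr, nc]
                and abs(img[nr, nc] - mean) <= delta
            ):
                mask[nr, nc] = True
                queue.append((nr, nc))
    return mask


def bf_dilate(mask, footprint, origin):
    """Per-pixel reflected-footprint overlap test."""
    mask = np.asarray(mask, dtype=bool)
    rows, cols = mask.shape
    out = np.zeros_like(mask)
    offs = [
        (r - origin[0], c - origin[1])
        for r in range(footprint.shape[0])
        for c in range(footprint.shape[1])
        if footprint[r, c]
    ]
    for r in range(rows):
        for c in range(cols):
            for dr, dc in offs:
                sr, sc = r - dr, c - dc
                if 0 <= sr < rows and 0 <= sc < cols and mask[sr, sc]:
                    out[r, c] = True
                    break
    return out


def bf_erode(mask, footprint, origin):
    """Per-pixel all-cells-covered test; outside the image counts false."""
    mask = np.asarray(mask, dtype=bool)
    rows, cols = mask.shape
    out = np.zeros_like(mask)
    offs = [
        (r - origin[0], c - origin[1])
        for r in range(footprint.shape[0])
        for c in range(footprint.shape[1])
        if footprint[r, c]
    ]
    for r in range(rows):
        for c in range(cols):
            ok = True
            for dr, dc in offs:
                sr, sc = r + dr, c + dc
                if not (0 <= sr < rows and 0 <= sc < cols and mask[sr, sc]):
                    ok = False
                    break
            out[r, c] = ok
    return out


def bf_median(img, window):
    """Sorted-neighborhood median with edge replication."""
    img = np.asarray(img)
    rows, cols = img.shape
    half = window // 2
    out = np.empty_like(img)
    for r in range(rows):
        for c in range(cols):
            vals = []
            for dr in range(-half, half + 1):
                for dc in range(-half, half + 1):
                    rr = min(max(r + dr, 0), rows - 1)
                    cc = min(max(c + dc, 0), cols - 1)
                    vals.append(img[rr, cc])
            vals.sort()
            out[r, c] = vals[len(vals) // 2]
    return out


def bf_nearest_neighbor(patterns, labels, x):
    """Label of the closest pattern in Euclidean distance."""
    d = [float(np.sum((np.asarray(p) - np.asarray(x)) ** 2)) for p in patterns]
    return labels[int(np.argmin(d))]
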