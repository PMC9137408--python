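"""Independent brute-force oracles used by the test suite.

These deliberately avoid the implementation's vectorized code paths:
plain Python loops and queues only.
"""

from __future__ import annotations

from collections import deque

import numpy as np


def brute_force_otsu(gray: np.ndarray) -> int | None:
    """Exhaustive between-class-variance maximization by plain loops."""
    values = np.asarray(gray).ravel().astype(int)
    if len(set(values.tolist())) < 2:
        return None
    best_t, best_var = None, -1.0
    n = values.size
    for t in range(256):
        lo = values[values <= t]
        hi = values[values > t]
        if lo.size == 0 or hi.size == 0:
            var = 0.0
        else:
            w0 = lo.size / n
            w1 = hi.size / n
            var = w0 * w1 * (lo.mean() - hi.mean()) ** 2
        if var > best_var:  # strict: keeps the smallest maximizer
            best_var, best_t = var, t
    return best_t


def flood_fill_components(mask: np.ndarray) -> list[set[tuple[int, int]]]:
    """8-connected components by breadth-first flood fill."""
    mask = np.asarray(mask, dtype=bool)
    seen = np.zeros_like(mask)
    comps = []
    h, w = mask.shape
    for r0 in range(h):
        for c0 in range(w):
            if mask[r0, c0] and not seen[r0, c0]:
                comp = set()
                queue = deque([(r0, c0)])
                seen[r0, c0] = True
                while queue:
                    r, c = queue.popleft()
                    comp.add((r, c))
                    for dr in (-1, 0, 1):
                        for dc in (-1, 0, 1):
                            rr, cc = r + dr, c + dc
                            if 0 <= rr < h and 0 <= cc < w and mask[rr, cc] and not seen[rr, cc]:
                                seen[rr, cc] = True
                                queue.append((rr, cc))
                comps.append(comp)
    return comps


def bfs_region_grow(
    gray: np.ndarray,
    seeds: np.ndarray,
    p: float,
    local_background: float,
    local_sd: float,
) -> np.ndarray:
    """Queue-based seeded growth: the reference fixed point.

    A neighbor q of an accepted center c joins iff
    |gray(q) - gray(c)| < gray(c) * p and gray(c) > background + sd.
    """
    gray = np.asarray(gray, dtype=float)
    mask = np.asarray(seeds, dtype=bool).copy()
    h, w = gray.shape
    floor = local_background + local_sd
    queue = deque(zip(*np.nonzero(mask)))
    while queue:
        r, c = queue.popleft()
        gc = gray[r, c]
        if gc <= floor:
            continue
        lim = gc * p
        for dr in (-1, 0, 1):
            for dc in (-1, 0, 1):
                if dr == 0 and dc == 0:
                    continue
                rr, cc = r + dr, c + dc
                if 0 <= rr < h and 0 <= cc < w and not mask[rr, cc]:
                    if abs(gray[rr, cc] - gc) < lim:
                        mask[rr, cc] = True
                        queue.append((rr, cc))
    return mask


def disc_pixel_count(radius: int) -> int:
    """Pixels within ``radius`` of a grid point (rasterized disc area)."""
    span = np.arange(-radius, radius + 1)
    rr, cc = np.meshgrid(span, span, indexing="ij")
    return int((rr * rr + cc * cc <= radius * radius).sum())
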