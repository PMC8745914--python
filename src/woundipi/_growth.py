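"""Seeded region growing on binary grids.

Implemented as breadth-first growth vectorized over whole frontiers: at every
step the current region is dilated by one pixel (4- or 8-neighbourhood) and
clipped to the admissible set, until a fixed point is reached. Because the
admissible set is static, the result is the set of admissible pixels reachable
from the seeds and is independent of any pixel visiting order.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage


def structuring_element(connectivity: int) -> np.ndarray:
    if connectivity == 4:
        return np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool)
    if connectivity == 8:
        return np.ones((3, 3), dtype=bool)
    raise ValueError(f"connectivity must be 4 or 8, got {connectivity}")


def grow(seeds: np.ndarray, allowed: np.ndarray, connectivity: int = 8) -> np.ndarray:
    """Grow from ``seeds`` through ``allowed`` pixels; returns a bool array.

    Seed pixels outside ``allowed`` are dropped. Growth admits a pixel iff it
    is adjacent (under ``connectivity``) to an already-grown pixel and belongs
    to ``allowed``.
    """
    seeds = np.asarray(seeds, dtype=bool)
    allowed = np.asarray(allowed, dtype=bool)
    if seeds.shape != allowed.shape:
        raise ValueError("seeds and allowed grids must share a shape")
    structure = structuring_element(connectivity)
    region = seeds & allowed
    if not region.any():
        return region
    h, w = region.shape
    # the region is confined to an expanding bounding window, so each step
    # costs in proportion to the grown area rather than the full frame
    rows = np.flatnonzero(region.any(axis=1))
    cols = np.flatnonzero(region.any(axis=0))
    r0, r1 = int(rows[0]), int(rows[-1]) + 1
    c0, c1 = int(cols[0]), int(cols[-1]) + 1
    while True:
        r0, r1 = max(r0 - 1, 0), min(r1 + 1, h)
        c0, c1 = max(c0 - 1, 0), min(c1 + 1, w)
        window = np.s_[r0:r1, c0:c1]
        sub = region[window]
        nxt = ndimage.binary_dilation(sub, structure=structure) & allowed[window]
        if nxt.sum() == sub.sum():
            return region
        region[window] = nxt
        rows = np.flatnonzero(nxt.any(axis=1))
        cols = np.flatnonzero(nxt.any(axis=0))
        r0, r1 = r0 + int(rows[0]), r0 + int(rows[-1]) + 1
        c0, c1 = c0 + int(cols[0]), c0 + int(cols[-1]) + 1
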