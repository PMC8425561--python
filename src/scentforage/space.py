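"""Toroidal geometry primitives.

The meadow is a continuous square torus of side ``size_map``: opposite
edges are identified, so there are no boundary effects on movement and
every point has a full neighbourhood.  All coordinates live in
``[0, size_map)`` and distances use the minimum-image convention.
"""

from __future__ import annotations

import math

import numpy as np

__all__ = ["wrap", "torus_distance", "torus_distance_brute"]


def wrap(x: float, y: float, size_map: float) -> tuple[float, float]:
    """Wrap a point onto the torus ``[0, size_map) x [0, size_map)``.

    Idempotent; the result is congruent to the input modulo ``size_map``.
    """
    if size_map <= 0:
        raise ValueError(f"size_map must be positive, got {size_map}")
    if not (math.isfinite(x) and math.isfinite(y)):
        raise ValueError(f"non-finite coordinates ({x}, {y})")
    # fp rounding can make a tiny negative fold onto size_map exactly
    wx = x % size_map
    wy = y % size_map
    return wx if wx < size_map else 0.0, wy if wy < size_map else 0.0


def torus_distance(x1: float, y1: float, x2: float, y2: float, size_map: float) -> float:
    """Euclidean distance between two points under the minimum-image convention.

    Symmetric, zero iff the points coincide on the torus, and bounded above
    by ``size_map * sqrt(2) / 2``.
    """
    dx = abs(x1 - x2) % size_map
    dy = abs(y1 - y2) % size_map
    dx = min(dx, size_map - dx)
    dy = min(dy, size_map - dy)
    return math.hypot(dx, dy)


def torus_distance_brute(x1: float, y1: float, x2: float, y2: float, size_map: float) -> float:
    """Reference distance via explicit minimisation over the 9 periodic images.

    Slow but transparent; used as an independent oracle in tests.
    """
    best = math.inf
    for ix in (-1, 0, 1):
        for iy in (-1, 0, 1):
            d = math.hypot(x1 - (x2 + ix * size_map), y1 - (y2 + iy * size_map))
            best = min(best, d)
    return best


def pairwise_torus_distances(points: np.ndarray, query: np.ndarray, size_map: float) -> np.ndarray:
    """Vectorised minimum-image distances from one query point to many points."""
    d = np.abs(points - query) % size_map
    d = np.minimum(d, size_map - d)
    return np.hypot(d[:, 0], d[:, 1])
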