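"""24-2 test-pattern geometry.

All computation in this package runs in right-eye orientation: positive x is
temporal, positive y is superior, coordinates in degrees of visual angle.
The 24-2 pattern places 54 stimuli on a 6-degree lattice (odd multiples of 3),
extending 21-27 degrees from fixation, with one extra nasal column at 27
degrees on the two rows straddling the horizontal meridian.  The physiologic
blind spot covers the two temporal points at (15, +-3).
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np

#: x-offsets per row, keyed by |y|; nasal (negative-x) side carries the extra
#: 27-degree point on the |y| = 3 rows.
_ROW_EXTENTS = {21: 9, 15: 15, 9: 21, 3: 21}

BLIND_SPOT = ((15, 3), (15, -3))


@dataclass(frozen=True)
class GridPoint:
    """One 24-2 stimulus location (right-eye orientation)."""

    x: int
    y: int
    is_blind_spot: bool = False

    def __post_init__(self) -> None:
        for c in (self.x, self.y):
            if abs(c) > 27 or c % 3 != 0 or (c // 3) % 2 == 0:
                raise ValueError(f"24-2 coordinates are odd multiples of 3 in [-27,27]; got {(self.x, self.y)}")


@lru_cache(maxsize=1)
def make_grid_24_2() -> tuple[GridPoint, ...]:
    """Canonical 54-point 24-2 layout, right-eye orientation.

    Points are ordered top-to-bottom (y descending) then nasal-to-temporal
    (x ascending), the order used for every 54-vector in this package.
    Row widths are 4/6/8/9/9/8/6/4; the |y|=3 rows gain the extra nasal point
    at x = -27.  Blind-spot points (15, +-3) are flagged.
    """
    points = []
    for y in (21, 15, 9, 3, -3, -9, -15, -21):
        ext = _ROW_EXTENTS[abs(y)]
        xs = list(range(-ext, ext + 1, 6))
        if abs(y) == 3:
            xs = [-27] + xs
        for x in xs:
            points.append(GridPoint(x, y, is_blind_spot=(x, y) in BLIND_SPOT))
    assert len(points) == 54
    return tuple(points)


@lru_cache(maxsize=1)
def grid_coordinates() -> np.ndarray:
    """(54, 2) int array of (x, y) in canonical order."""
    return np.array([(p.x, p.y) for p in make_grid_24_2()])


@lru_cache(maxsize=1)
def blind_spot_mask() -> np.ndarray:
    """Boolean (54,) mask, True at the two blind-spot indices."""
    return np.array([p.is_blind_spot for p in make_grid_24_2()])


@lru_cache(maxsize=1)
def seeing_indices() -> np.ndarray:
    """Indices of the 52 non-blind-spot points, canonical order."""
    return np.flatnonzero(~blind_spot_mask())


@lru_cache(maxsize=1)
def left_grid_coordinates() -> np.ndarray:
    """(54, 2) coordinates of the left-eye 24-2 lattice, canonical order.

    A left eye's nasal field is its right half, so its lattice is the
    x -> -x reflection of the right-eye lattice (extra nasal column at
    x = +27 on the |y| = 3 rows), ordered the same way: y descending,
    then x ascending.
    """
    pts = [(-x, y) for x, y in grid_coordinates()]
    pts.sort(key=lambda p: (-p[1], p[0]))
    return np.array(pts)


@lru_cache(maxsize=1)
def mirror_permutation() -> np.ndarray:
    """Permutation p with td_right[i] = td_left[p[i]].

    Brings a left-eye field (stored on the left lattice in canonical order)
    into right-eye orientation: the right-eye point (x, y) receives the
    left-eye value tested at (-x, y).  Applying the same permutation to a
    right-oriented vector returns it to left ordering, so the operation is
    an involution at the value level.
    """
    coords = grid_coordinates()
    left = left_grid_coordinates()
    index = {(x, y): i for i, (x, y) in enumerate(left)}
    perm = np.array([index[(-x, y)] for x, y in coords])
    return perm


def neighbor_pairs(cross_midline: bool = True) -> np.ndarray:
    """(n, 2) index pairs of 8-neighborhood adjacency on the 24-2 lattice.

    Two points are neighbors when both |dx| and |dy| are <= 6 degrees (one
    lattice step, including diagonals).  With ``cross_midline=False`` pairs
    spanning the horizontal meridian (y changing sign) are dropped, for
    hemifield-respecting cluster rules.
    """
    coords = grid_coordinates()
    pairs = []
    for i in range(54):
        for j in range(i + 1, 54):
            dx = abs(coords[i, 0] - coords[j, 0])
            dy = abs(coords[i, 1] - coords[j, 1])
            if dx <= 6 and dy <= 6:
                if not cross_midline and coords[i, 1] * coords[j, 1] < 0:
                    continue
                pairs.append((i, j))
    return np.array(pairs)
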