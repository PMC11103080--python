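"""Agreement metrics for annotation geometry.

Two metrics cover the two annotation styles:

* **Dice overlap** for enclosed regions (arteries, muscles, nerves).
  Both outlines are rasterized onto the scan's pixel grid and the score is
  ``2 |A ∩ B| / (|A| + |B|)``: 1 for identical areas, 0 for disjoint ones.

* **Normalized Hausdorff distance** for line annotations (fascial and
  serosal planes).  Each polyline is resampled to a dense point chain; the
  directed distance is the maximum over points of one chain of the
  distance to the nearest point of the other; the symmetric distance is
  the larger of the two directions.  Dividing by an image-size denominator
  maps the score to [0, 1]: 0 for identical lines, 1 for lines separated
  by the full image extent.

Rasterization uses pixel-centre containment under the even-odd fill rule:
pixel (row i, column j) is inside iff its centre (j + 0.5, i + 0.5) is
inside the polygon.  The even-odd rule makes the behaviour of
self-intersecting hand-drawn outlines deterministic.  This primitive is
deliberately written out in full (a vectorized crossing-number test)
because the downstream scores inherit its exact boundary semantics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import numpy as np
from scipy.spatial.distance import directed_hausdorff as _scipy_directed_hausdorff

__all__ = [
    "RasterMask",
    "PointChain",
    "rasterize",
    "dice",
    "resample_chain",
    "resample_components",
    "directed_hausdorff",
    "hausdorff_score",
]

DEFAULT_RESAMPLE_SPACING = 0.5  # px; sub-pixel densification before Hausdorff

DenominatorMode = Literal["max_side", "diagonal"]


@dataclass
class RasterMask:
    """Binary occupancy grid on a scan's pixel lattice."""

    grid: np.ndarray  # bool, shape (height, width)
    scan_id: str | None = None

    def __post_init__(self):
        self.grid = np.asarray(self.grid, dtype=bool)
        if self.grid.ndim != 2:
            raise ValueError("mask grid must be 2-D")

    @property
    def area(self) -> int:
        return int(self.grid.sum())


@dataclass
class PointChain:
    """Densified point sampling of a (possibly multi-part) polyline."""

    points: np.ndarray  # float, shape (n, 2)
    resample_spacing: float

    def __post_init__(self):
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 2:
            raise ValueError("chain points must have shape (n, 2)")

    def __len__(self) -> int:
        return len(self.points)


def _as_grid(mask) -> np.ndarray:
    return mask.grid if isinstance(mask, RasterMask) else np.asarray(mask, dtype=bool)


def _polygon_parity(vertices: np.ndarray, width: int, height: int) -> np.ndarray:
    """Even-odd containment of every pixel centre in one polygon.

    Crossing-number test: a pixel centre is inside iff a leftward ray
    crosses an odd number of edges.  Vectorized over the polygon's
    bounding box only.
    """
    v = np.asarray(vertices, dtype=float)
    out = np.zeros((height, width), dtype=bool)
    if len(v) < 3:
        return out
    j0 = max(int(np.floor(v[:, 0].min() - 0.5)), 0)
    j1 = min(int(np.ceil(v[:, 0].max() + 0.5)), width - 1)
    i0 = max(int(np.floor(v[:, 1].min() - 0.5)), 0)
    i1 = min(int(np.ceil(v[:, 1].max() + 0.5)), height - 1)
    if j1 < j0 or i1 < i0:
        return out
    xs = np.arange(j0, j1 + 1) + 0.5  # (w,)
    ys = (np.arange(i0, i1 + 1) + 0.5)[:, None]  # (h, 1)
    parity = np.zeros((i1 - i0 + 1, j1 - j0 + 1), dtype=bool)
    x1, y1 = v[:, 0], v[:, 1]
    x2, y2 = np.roll(x1, -1), np.roll(y1, -1)  # implicit closure
    for ex1, ey1, ex2, ey2 in zip(x1, y1, x2, y2):
        if ey1 == ey2:
            continue  # horizontal edges never cross a horizontal ray test
        spans = (ey1 <= ys) != (ey2 <= ys)  # (h, 1)
        x_at = ex1 + (ys - ey1) * (ex2 - ex1) / (ey2 - ey1)  # (h, 1)
        parity ^= spans & (xs[None, :] < x_at)
    out[i0 : i1 + 1, j0 : j1 + 1] = parity
    return out


def rasterize(components: Iterable[Sequence], width: int, height: int,
              scan_id: str | None = None) -> RasterMask:
    """Rasterize a set of closed polygons to a binary mask.

    Each component is filled under the even-odd rule; the mask is the
    union of the filled components.  An empty component list yields an
    all-zero mask.
    """
    if width <= 0 or height <= 0:
        raise ValueError(f"non-positive mask dimensions {width} x {height}")
    grid = np.zeros((height, width), dtype=bool)
    for comp in components:
        comp = np.asarray(comp, dtype=float)
        if len(comp) < 3:
            raise ValueError(f"polygon needs >= 3 vertices, got {len(comp)}")
        grid |= _polygon_parity(comp, width, height)
    return RasterMask(grid, scan_id)


def dice(a, b, *, both_empty: float = math.nan) -> float:
    """Dice overlap coefficient of two masks on the same grid.

    Returns ``2 |A ∩ B| / (|A| + |B|)``.  When both masks are empty the
    metric is undefined; ``both_empty`` (default NaN) is returned so the
    caller can exclude or score such pairs by policy.
    """
    ga, gb = _as_grid(a), _as_grid(b)
    if ga.shape != gb.shape:
        raise ValueError(f"mask shapes differ: {ga.shape} vs {gb.shape}")
    na, nb = int(ga.sum()), int(gb.sum())
    if na == 0 and nb == 0:
        return both_empty
    inter = int(np.logical_and(ga, gb).sum())
    return 2.0 * inter / (na + nb)


def _resample_part(vertices: np.ndarray, spacing: float) -> np.ndarray:
    """Arc-length resampling of one polyline part.

    Points are placed at uniform arc-length intervals no larger than
    ``spacing``; the first and last original vertices are always kept.
    """
    v = np.asarray(vertices, dtype=float)
    seg = np.diff(v, axis=0)
    seglen = np.hypot(seg[:, 0], seg[:, 1])
    cum = np.concatenate([[0.0], np.cumsum(seglen)])
    total = cum[-1]
    if total == 0.0:
        return v[:1]
    n_int = max(int(np.ceil(total / spacing)), 1)
    targets = np.linspace(0.0, total, n_int + 1)
    x = np.interp(targets, cum, v[:, 0])
    y = np.interp(targets, cum, v[:, 1])
    return np.column_stack([x, y])


def resample_chain(points: Sequence, spacing: float = DEFAULT_RESAMPLE_SPACING) -> PointChain:
    """Resample one polyline at arc-length intervals <= ``spacing`` px."""
    pts = np.asarray(points, dtype=float)
    if len(pts) < 2:
        raise ValueError(f"polyline needs >= 2 vertices, got {len(pts)}")
    if spacing <= 0:
        raise ValueError("spacing must be positive")
    return PointChain(_resample_part(pts, spacing), spacing)


def resample_components(components: Iterable[Sequence],
                        spacing: float = DEFAULT_RESAMPLE_SPACING) -> PointChain:
    """Resample every part of a multi-part polyline and pool the points.

    Grouped line structures (e.g. the two layers of the rectus sheath)
    are compared as one pooled point set.
    """
    parts = [resample_chain(c, spacing).points for c in components]
    if not parts:
        raise ValueError("no polyline components to resample")
    return PointChain(np.vstack(parts), spacing)


def _chain_points(chain) -> np.ndarray:
    pts = chain.points if isinstance(chain, PointChain) else np.asarray(chain, dtype=float)
    if len(pts) == 0:
        raise ValueError("empty point chain; empties must be handled upstream")
    return pts


def directed_hausdorff(a, b) -> float:
    """Directed Hausdorff distance from chain ``a`` to chain ``b`` in px:
    max over points p of a of the distance from p to the nearest point of b.
    """
    pa, pb = _chain_points(a), _chain_points(b)
    d, _, _ = _scipy_directed_hausdorff(pa, pb)
    return float(d)


def hausdorff_score(a, b, width: int, height: int, *,
                    symmetrize: bool = True,
                    denominator_mode: DenominatorMode = "max_side") -> float:
    """Normalized Hausdorff agreement score in [0, 1]; lower is better.

    The raw distance (directed a→b, or the symmetric max of both
    directions) is divided by an image-size denominator — the larger image
    side by default, or the diagonal — and clamped at 1.
    """
    raw = directed_hausdorff(a, b)
    if symmetrize:
        raw = max(raw, directed_hausdorff(b, a))
    if denominator_mode == "max_side":
        denom = float(max(width, height))
    elif denominator_mode == "diagonal":
        denom = math.hypot(width, height)
    else:
        raise ValueError(f"unknown denominator_mode {denominator_mode!r}")
    if denom <= 0:
        raise ValueError("image dimensions must be positive")
    return min(1.0, raw / denom)
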