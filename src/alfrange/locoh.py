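"""k-LoCoH occurrence distributions: local hulls, isopleths, use raster.

The occurrence distribution (OD) of a fold is estimated with the
fixed-k Local Convex Hull method: the convex hull of each fix and its
k-1 nearest neighbors is built, hulls are sorted by area, and their
cumulative union is tracked until it covers a stated fraction of the
fixes. Nine nested isopleths (15%...95% by default) delineate
progressively less intensely used space; rasterizing the isopleth bands
(innermost band scored 9, outermost 1, then normalized to sum to 1)
yields the use-intensity surface that the selection analysis weights
attribute rasters by.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import shapely
from shapely.geometry import MultiPoint, Polygon
from shapely.ops import unary_union

from .grids import GridSpec

DEFAULT_LEVELS = (0.15, 0.25, 0.35, 0.45, 0.55, 0.65, 0.75, 0.85, 0.95)

# sliver buffer for degenerate (collinear / duplicate) hulls, meters
_DEGENERATE_BUFFER = 1e-6


def default_k(n: int) -> int:
    """Standard k heuristic: sqrt of the number of fixes, at least 3."""
    return max(3, math.ceil(math.sqrt(n)))


@dataclass(frozen=True)
class LocohConfig:
    k: int | None = None  # None -> default_k(n) per fold
    isopleth_levels: tuple[float, ...] = DEFAULT_LEVELS

    def __post_init__(self) -> None:
        lv = self.isopleth_levels
        if not lv or any(not 0 < l <= 1 for l in lv) or any(
            b <= a for a, b in zip(lv, lv[1:])
        ):
            raise ValueError("isopleth levels must be strictly increasing in (0, 1]")
        if self.k is not None and self.k < 3:
            raise ValueError("k must be >= 3")


@dataclass
class LocalHull:
    focal_index: int
    neighbor_indices: np.ndarray  # includes the focal point
    polygon: Polygon
    area: float


@dataclass
class IsoplethSet:
    levels: tuple[float, ...]
    polygons: list  # (Multi)Polygon per level, nested by construction
    covered_fractions: list[float]
    hulls: list[LocalHull] = field(default_factory=list, repr=False)

    def polygon_at(self, level: float):
        return self.polygons[self.levels.index(level)]

    @property
    def od95(self):
        """The outermost (95% by default) isopleth polygon."""
        return self.polygons[-1]


@dataclass
class UseRaster:
    grid: GridSpec
    values: np.ndarray  # non-negative, sums to 1

    def __post_init__(self) -> None:
        if self.values.shape != self.grid.shape:
            raise ValueError("use raster shape does not match grid")


def _knn_indices(points: np.ndarray, k: int) -> np.ndarray:
    """Indices of each point's k nearest neighbors (self included).

    Distance ties are broken by point index so runs are reproducible
    across platforms; complexity is O(n^2 log n), fine at telemetry fold
    sizes (tens to low thousands of fixes).
    """
    n = len(points)
    d2 = np.sum((points[:, None, :] - points[None, :, :]) ** 2, axis=-1)
    idx = np.arange(n)
    out = np.empty((n, k), dtype=np.int64)
    for i in range(n):
        order = np.lexsort((idx, d2[i]))
        out[i] = order[:k]
    return out


def local_hulls(points: np.ndarray, k: int) -> list[LocalHull]:
    """Convex hull of each point plus its k-1 nearest neighbors.

    Degenerate hulls (duplicate or collinear coordinates) are kept with
    area 0 and a hair-width buffer so the cumulative union stays valid
    and the hull count always equals the number of points.
    """
    points = np.asarray(points, dtype=float)
    n = len(points)
    if k < 3:
        raise ValueError("k must be >= 3")
    if n < k:
        raise ValueError(f"need at least k={k} points, got {n}")
    nbrs = _knn_indices(points, k)
    hulls: list[LocalHull] = []
    for i in range(n):
        hull = MultiPoint(points[nbrs[i]]).convex_hull
        if hull.geom_type == "Polygon":
            area = hull.area
        else:  # point or line: degenerate
            area = 0.0
            hull = hull.buffer(_DEGENERATE_BUFFER)
        hulls.append(LocalHull(i, nbrs[i], hull, float(area)))
    return hulls


def build_isopleths(
    hulls: list[LocalHull],
    points: np.ndarray,
    levels: tuple[float, ...] = DEFAULT_LEVELS,
) -> IsoplethSet:
    """Cumulative-union isopleths at the requested coverage levels.

    Hulls are added smallest-area first (ties by focal index); the
    isopleth at level ``l`` is the smallest running union covering at
    least a fraction ``l`` of the points. Later levels extend earlier
    ones, so the polygons nest exactly.
    """
    if not hulls:
        raise ValueError("empty hull set")
    points = np.asarray(points, dtype=float)
    n = len(points)
    order = sorted(range(len(hulls)), key=lambda i: (hulls[i].area, hulls[i].focal_index))
    pts_geom = shapely.points(points)
    covered = np.zeros(n, dtype=bool)

    polygons = []
    fractions = []
    level_iter = iter(levels)
    target = next(level_iter)
    running = None
    done = False
    pieces: list = []  # hull polygons since the last union snapshot
    for j in order:
        pieces.append(hulls[j].polygon)
        new = shapely.covers(hulls[j].polygon, pts_geom[~covered])
        if new.any():
            covered[np.flatnonzero(~covered)[new]] = True
        frac = covered.sum() / n
        while frac >= target - 1e-12:
            running = unary_union([running, *pieces]) if running is not None else unary_union(pieces)
            pieces = []
            polygons.append(running)
            fractions.append(float(frac))
            try:
                target = next(level_iter)
            except StopIteration:
                done = True
                break
        if done:
            break
    # coverage can top out below late levels only through numeric edge
    # cases; close any remaining levels with the full union
    while len(polygons) < len(levels):
        running = unary_union([running, *pieces]) if running is not None else unary_union(pieces)
        pieces = []
        polygons.append(running)
        fractions.append(float(covered.sum() / n))
    return IsoplethSet(tuple(levels), polygons, fractions, hulls)


def od_intensity_raster(isopleths: IsoplethSet, grid: GridSpec) -> UseRaster:
    """Rasterize isopleth bands into a normalized use-intensity surface.

    A cell center inside the innermost isopleth scores 9, inside the next
    band 8, ... inside only the outermost band 1, outside 0; scores are
    then divided by their total so the raster sums to 1.
    """
    n_levels = len(isopleths.levels)
    if n_levels != 9:
        raise ValueError(f"expected 9 isopleth levels, got {n_levels}")
    outer = isopleths.polygons[-1]
    minx, miny, maxx, maxy = outer.bounds
    r0, c0 = grid.cell_index(max(minx, grid.x0), max(miny, grid.y0))
    r1, c1 = grid.cell_index(min(maxx, grid.xmax - 1e-9), min(maxy, grid.ymax - 1e-9))
    r0, c0 = max(int(r0), 0), max(int(c0), 0)
    r1, c1 = min(int(r1), grid.nrows - 1), min(int(c1), grid.ncols - 1)

    xs = grid.x0 + (np.arange(c0, c1 + 1) + 0.5) * grid.cell
    ys = grid.y0 + (np.arange(r0, r1 + 1) + 0.5) * grid.cell
    X, Y = np.meshgrid(xs, ys)
    centers = shapely.points(np.column_stack([X.ravel(), Y.ravel()]))

    raw_win = np.zeros(X.size)
    inside_outer = shapely.covers(outer, centers)
    sel = np.flatnonzero(inside_outer)
    # nested polygons: membership in each level adds one to the score,
    # so a cell inside the innermost of 9 levels scores 9
    raw_win[sel] += 1.0
    for poly in isopleths.polygons[-2::-1]:
        if len(sel) == 0:
            break
        inner = shapely.covers(poly, centers[sel])
        sel = sel[inner]
        raw_win[sel] += 1.0

    raw = np.zeros(grid.shape)
    raw[r0 : r1 + 1, c0 : c1 + 1] = raw_win.reshape(X.shape)
    total = raw.sum()
    if total == 0:
        raise ValueError(
            "outermost isopleth covers no cell centers; OD smaller than one cell"
        )
    return UseRaster(grid=grid, values=raw / total)


def estimate_od(
    points: np.ndarray, config: LocohConfig | None = None
) -> IsoplethSet:
    """Convenience wrapper: hulls + isopleths with the configured k."""
    config = config or LocohConfig()
    points = np.asarray(points, dtype=float)
    k = config.k if config.k is not None else default_k(len(points))
    k = min(k, len(points))
    hulls = local_hulls(points, k)
    return build_isopleths(hulls, points, config.isopleth_levels)
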