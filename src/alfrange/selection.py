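"""Selection ratios: intensity-weighted use versus availability.

For each fold and habitat attribute j the log selection ratio is

    logSR_j = log(used_j / available_j)

where ``used_j`` is the use-raster-weighted average of the attribute
(the use raster sums to 1, so multiplying and summing is a weighted
mean) and ``available_j`` is the plain mean of the attribute over a
standardized 100-km^2 availability square anchored at the fix closest
to the OD centroid. logSR > 0 is selection, < 0 avoidance, 0 use in
proportion to availability.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .grids import GridSpec, require_same_grid
from .locoh import UseRaster

DOMAIN_SIDE_M = 10_000.0  # 100 km^2 square


@dataclass(frozen=True)
class AvailabilityDomain:
    anchor: tuple[float, float]
    side: float
    rows: tuple[int, int]  # [row_lo, row_hi) on the template grid
    cols: tuple[int, int]
    clipped: bool  # True when the square ran past the grid edge

    @property
    def n_cells(self) -> int:
        return (self.rows[1] - self.rows[0]) * (self.cols[1] - self.cols[0])

    def window(self, raster: np.ndarray) -> np.ndarray:
        return raster[self.rows[0] : self.rows[1], self.cols[0] : self.cols[1]]


@dataclass(frozen=True)
class SelectionRecord:
    fold_id: str
    attribute: str
    used: float
    available: float
    log_sr: float  # NaN when available == 0 (record undefined)
    zero_adjusted: bool


def availability_domain(
    fold_points: np.ndarray,
    isopleth95,
    grid: GridSpec,
    side: float = DOMAIN_SIDE_M,
) -> AvailabilityDomain:
    """Square availability window centered on the fix nearest the OD centroid.

    The window contains the template cells whose centers fall in
    ``[anchor - side/2, anchor + side/2)`` on each axis (half-open, so a
    center sitting exactly on the max edge is excluded); it is clipped to
    the grid with a flag when the anchor sits near the edge.
    """
    fold_points = np.asarray(fold_points, dtype=float)
    if len(fold_points) == 0:
        raise ValueError("fold has no fixes")
    centroid = isopleth95.centroid
    d2 = (fold_points[:, 0] - centroid.x) ** 2 + (fold_points[:, 1] - centroid.y) ** 2
    anchor = tuple(fold_points[int(np.argmin(d2))])  # argmin is stable: earliest fix wins ties

    half = side / 2.0
    xs = grid.x_centers()
    ys = grid.y_centers()
    col_in = np.flatnonzero((xs >= anchor[0] - half) & (xs < anchor[0] + half))
    row_in = np.flatnonzero((ys >= anchor[1] - half) & (ys < anchor[1] + half))
    if len(col_in) == 0 or len(row_in) == 0:
        raise ValueError("availability window contains no grid cells")
    full_cells = int(side // grid.cell) + (0 if (side / grid.cell).is_integer() else 1)
    clipped = len(col_in) < full_cells - 1 or len(row_in) < full_cells - 1
    return AvailabilityDomain(
        anchor=anchor,
        side=side,
        rows=(int(row_in[0]), int(row_in[-1]) + 1),
        cols=(int(col_in[0]), int(col_in[-1]) + 1),
        clipped=clipped,
    )


def weighted_use(use_raster: UseRaster, attribute: np.ndarray, grid: GridSpec | None = None) -> float:
    """Use-weighted average of the attribute: sum(use * attribute)."""
    if grid is not None:
        require_same_grid(use_raster.grid, grid)
    if attribute.shape != use_raster.values.shape:
        raise ValueError("attribute raster not co-registered with use raster")
    return float(np.sum(use_raster.values * attribute))


def mean_availability(attribute: np.ndarray, domain: AvailabilityDomain) -> float:
    """Mean attribute value over the availability window (NaNs excluded)."""
    window = domain.window(attribute)
    if window.size == 0:
        raise ValueError("empty availability window")
    return float(np.nanmean(window))


def log_selection_ratio(
    used: float, available: float, n_domain_cells: int
) -> tuple[float, bool]:
    """Eq. logSR with explicit zero handling.

    used = 0 (common for sparse binary ALF rasters) is floored at half of
    one cell's share of the domain, delta = 1 / (2 * n_domain_cells), and
    flagged; available = 0 makes the ratio undefined and returns NaN so
    the fold drops out of that attribute's models.
    """
    if used < 0 or available < 0:
        raise ValueError("used and available must be non-negative")
    if available == 0:
        return float("nan"), False
    if used == 0:
        delta = 1.0 / (2.0 * n_domain_cells)
        return math.log(delta / available), True
    return math.log(used / available), False


def selection_records(
    fold_id: str,
    use_raster: UseRaster,
    attributes: dict[str, np.ndarray],
    domain: AvailabilityDomain,
) -> list[SelectionRecord]:
    """logSR for every attribute of one fold."""
    records = []
    for name, raster in attributes.items():
        used = weighted_use(use_raster, raster)
        avail = mean_availability(raster, domain)
        log_sr, adjusted = log_selection_ratio(used, avail, domain.n_cells)
        records.append(
            SelectionRecord(
                fold_id=fold_id,
                attribute=name,
                used=used,
                available=avail,
                log_sr=log_sr,
                zero_adjusted=adjusted,
            )
        )
    return records
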