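"""Home-range size and shape responses from the outermost isopleth.

The shape index compares the perimeter of the occurrence distribution
to the circumference of the circle of equal area,

    SI = P / (2 * pi * sqrt(A / pi)),

so SI = 1 for a circle and grows with elongation and boundary
complexity. Because SI lives on (1, inf), it is log-transformed twice
before modeling, mapping it onto the whole real line.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from shapely.geometry.base import BaseGeometry

# floor applied before the double log: rasterized near-circular ODs can
# come out a hair below the theoretical minimum of 1
SI_CLAMP_EPS = 1e-6


@dataclass(frozen=True)
class ShapeMetrics:
    area_m2: float
    perimeter_m: float
    shape_index: float
    log_area: float
    loglog_si: float


def area_perimeter(isopleth95: BaseGeometry) -> tuple[float, float]:
    """Total area and total boundary length of the 95% isopleth.

    Multi-part geometries contribute every part; holes subtract from the
    area but their rings *add* to the perimeter (an animal skirting an
    interior gap still travels that boundary).
    """
    if isopleth95 is None or isopleth95.is_empty:
        raise ValueError("empty isopleth geometry")
    if isopleth95.geom_type not in ("Polygon", "MultiPolygon"):
        raise ValueError(f"expected polygonal geometry, got {isopleth95.geom_type}")
    # shapely's length of a polygon already sums exterior and interior rings
    return float(isopleth95.area), float(isopleth95.length)


def shape_index(area_m2: float, perimeter_m: float) -> float:
    if area_m2 <= 0 or perimeter_m <= 0:
        raise ValueError("area and perimeter must be positive")
    return perimeter_m / (2.0 * math.sqrt(math.pi * area_m2))


def si_transform(si: float) -> float:
    """Double log of the shape index, clamped just above 1."""
    if si < 1.0 - 1e-9:
        raise ValueError(f"shape index {si} below the isoperimetric minimum")
    return math.log(math.log(max(si, 1.0 + SI_CLAMP_EPS)))


def shape_metrics(isopleth95: BaseGeometry) -> ShapeMetrics:
    a, p = area_perimeter(isopleth95)
    si = shape_index(a, p)
    return ShapeMetrics(
        area_m2=a,
        perimeter_m=p,
        shape_index=si,
        log_area=math.log(a),
        loglog_si=si_transform(si),
    )
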