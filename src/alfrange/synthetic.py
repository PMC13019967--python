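"""Synthetic landscapes, linear-feature networks, and GPS tracks.

Real ungulate collar data and the remote-sensing products behind the
habitat attributes are restricted, so the pipeline is exercised on
simulated inputs with *known* selection and permeability parameters:

* :func:`gen_landscape` draws each habitat attribute (elevation,
  roughness, forage, shrub, tree, snow) as a stationary Gaussian random
  field with a per-attribute correlation length, on the shared 30-m grid.
* :func:`gen_alf_lines` lays down road / fence line networks at a
  requested length density (km of line per km^2).
* :func:`simulate_track` runs a discrete-time biased random walk with
  Ornstein-Uhlenbeck-style attraction to a home center, endpoint habitat
  weighting, and probabilistic rejection of steps that cross a linear
  feature (the feature's permeability = crossing probability).

Every generator is deterministic given its seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from shapely import STRtree
from shapely.geometry import LineString

from .grids import GridSpec

ATTRIBUTES = ("elevation", "roughness", "forage", "shrub", "tree", "snow")
ALF_TYPES = ("paved", "unpaved", "fence")

WINTER_MONTH = 2
SUMMER_MONTH = 7


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------
@dataclass
class LandscapeBundle:
    """Co-registered habitat attribute rasters and binary ALF rasters."""

    grid: GridSpec
    attributes: dict[str, np.ndarray]
    alf: dict[str, np.ndarray]
    alf_lines: dict[str, list[LineString]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, arr in {**self.attributes, **self.alf}.items():
            if arr.shape != self.grid.shape:
                raise ValueError(f"raster '{name}' shape {arr.shape} != grid {self.grid.shape}")
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"raster '{name}' contains non-finite values")
        for name, arr in self.alf.items():
            if not np.isin(arr, (0, 1)).all():
                raise ValueError(f"ALF raster '{name}' must be binary 0/1")
        rough = self.attributes.get("roughness")
        if rough is not None and (rough < 0).any():
            raise ValueError("roughness raster must be non-negative")


@dataclass
class MovementParams:
    """Parameters of the simulated home-ranging walk."""

    home_center: tuple[float, float]
    attraction_rate: float = 0.15  # 1/h: pull toward home_center
    step_scale: float = 250.0  # m: per-axis s.d. of a 2-h displacement
    habitat_beta: dict[str, float] = field(default_factory=dict)
    permeability: dict[str, float] = field(default_factory=dict)
    fix_interval: float = 2.0  # hours
    season_month: int = SUMMER_MONTH
    seed: int = 0
    max_retries: int = 20

    def __post_init__(self) -> None:
        if self.attraction_rate <= 0:
            raise ValueError("attraction_rate must be > 0")
        if self.step_scale <= 0:
            raise ValueError("step_scale must be > 0")
        for t, p in self.permeability.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"permeability[{t}]={p} outside [0, 1]")


@dataclass
class Track:
    """One animal's ordered GPS fixes."""

    animal_id: str
    species: str  # "deer" | "pronghorn"
    sex: str  # "F" | "M"
    timestamps: np.ndarray  # datetime64[s], strictly increasing
    x: np.ndarray
    y: np.ndarray

    def __post_init__(self) -> None:
        if len(self.timestamps) != len(self.x) or len(self.x) != len(self.y):
            raise ValueError("timestamps, x, y must have equal length")
        if len(self.timestamps) > 1 and not (np.diff(self.timestamps.astype("int64")) > 0).all():
            raise ValueError("timestamps must be strictly increasing")
        if not (np.isfinite(self.x).all() and np.isfinite(self.y).all()):
            raise ValueError("coordinates must be finite")

    def __len__(self) -> int:
        return len(self.timestamps)


# ---------------------------------------------------------------------------
# Gaussian random fields
# ---------------------------------------------------------------------------
@dataclass(frozen=True)
class FieldSpec:
    """One attribute's Gaussian-random-field parameters.

    ``corr_length`` is the distance (m) at which the correlation of the
    underlying unit-variance field drops to exp(-1/2); the covariance
    model is Gaussian: c(h) = exp(-h^2 / (2 L^2)).
    """

    corr_length: float  # m
    mean: float
    sd: float
    lo: float | None = None
    hi: float | None = None
    half_normal: bool = False  # value = sd * |z| (used for roughness)


DEFAULT_FIELD_SPECS: dict[str, FieldSpec] = {
    "elevation": FieldSpec(900.0, 2000.0, 120.0),
    "roughness": FieldSpec(300.0, 0.0, 15.0, half_normal=True),
    "forage": FieldSpec(400.0, 0.45, 0.15, lo=0.0, hi=1.0),
    "shrub": FieldSpec(400.0, 0.30, 0.12, lo=0.0, hi=1.0),
    "tree": FieldSpec(500.0, 0.25, 0.15, lo=0.0, hi=1.0),
    "snow": FieldSpec(600.0, 0.30, 0.10, lo=0.0),
}


def gaussian_random_field(nrows: int, ncols: int, corr_cells: float, rng: np.random.Generator) -> np.ndarray:
    """Stationary unit-variance field with Gaussian covariance.

    Sampled by circulant embedding on a doubled torus, so the marginal
    variance is exact regardless of the correlation length; when the
    correlation length exceeds the grid extent the realization within the
    window is close to constant, as it should be.
    """
    if corr_cells <= 0:
        return rng.standard_normal((nrows, ncols))
    M, N = 2 * nrows, 2 * ncols
    dy = np.minimum(np.arange(M), M - np.arange(M)).astype(float)
    dx = np.minimum(np.arange(N), N - np.arange(N)).astype(float)
    h2 = dy[:, None] ** 2 + dx[None, :] ** 2
    cov = np.exp(-h2 / (2.0 * corr_cells**2))
    lam = np.fft.fft2(cov).real
    lam = np.maximum(lam, 0.0)  # clip tiny negative embedding eigenvalues
    noise = rng.standard_normal((M, N)) + 1j * rng.standard_normal((M, N))
    y = np.fft.ifft2(np.sqrt(lam) * np.fft.fft2(noise))
    return y.real[:nrows, :ncols] / math.sqrt(2.0)


def gen_landscape(
    grid: GridSpec,
    field_specs: dict[str, FieldSpec] | None = None,
    seed: int = 0,
    season_month: int = SUMMER_MONTH,
) -> LandscapeBundle:
    """Generate attribute rasters (and empty ALF rasters) on ``grid``.

    Snow is a winter phenomenon: for any month other than February the
    snow raster is identically zero.
    """
    if grid.nrows < 50 or grid.ncols < 50:
        raise ValueError("grid too small: need at least 50x50 cells")
    specs = dict(DEFAULT_FIELD_SPECS)
    if field_specs:
        specs.update(field_specs)
    rng = np.random.default_rng(seed)
    attributes: dict[str, np.ndarray] = {}
    for name in ATTRIBUTES:
        spec = specs[name]
        if name == "snow" and season_month != WINTER_MONTH:
            attributes[name] = np.zeros(grid.shape)
            continue
        z = gaussian_random_field(grid.nrows, grid.ncols, spec.corr_length / grid.cell, rng)
        if spec.half_normal:
            vals = spec.sd * np.abs(z)
        else:
            vals = spec.mean + spec.sd * z
        if spec.lo is not None or spec.hi is not None:
            vals = np.clip(vals, spec.lo, spec.hi)
        attributes[name] = vals
    alf = {t: np.zeros(grid.shape, dtype=np.int8) for t in ALF_TYPES}
    return LandscapeBundle(grid=grid, attributes=attributes, alf=alf)


# ---------------------------------------------------------------------------
# linear-feature networks
# ---------------------------------------------------------------------------
def _partition_lines(grid: GridSpec, density: float, rng: np.random.Generator) -> list[LineString]:
    # spacing s (m) such that 2/s_km = density  =>  s = 2000/density m
    s = 2000.0 / density
    lines: list[LineString] = []
    x = grid.x0 + s
    while x < grid.xmax - 1e-9:
        lines.append(LineString([(x, grid.y0), (x, grid.ymax)]))
        x += s
    y = grid.y0 + s
    while y < grid.ymax - 1e-9:
        lines.append(LineString([(grid.x0, y), (grid.xmax, y)]))
        y += s
    return lines


def _random_segments(
    grid: GridSpec, target_m: float, rng: np.random.Generator, seg_len: float = 1500.0
) -> list[LineString]:
    extent = grid.extent_polygon()
    lines: list[LineString] = []
    total = 0.0
    while total < target_m - 1e-9:
        cx = rng.uniform(grid.x0, grid.xmax)
        cy = rng.uniform(grid.y0, grid.ymax)
        theta = rng.uniform(0, math.pi)
        dx, dy = 0.5 * seg_len * math.cos(theta), 0.5 * seg_len * math.sin(theta)
        seg = LineString([(cx - dx, cy - dy), (cx + dx, cy + dy)]).intersection(extent)
        if seg.is_empty or seg.length == 0:
            continue
        if seg.geom_type != "LineString":
            seg = max(seg.geoms, key=lambda g: g.length)
        remaining = target_m - total
        if seg.length > remaining:  # trim so the realized density is exact
            seg = LineString([seg.interpolate(0), seg.interpolate(remaining)])
        lines.append(seg)
        total += seg.length
    return lines


def gen_alf_lines(
    grid: GridSpec,
    density_per_type: dict[str, float],
    pattern: str = "random_segments",
    seed: int = 0,
) -> dict[str, list[LineString]]:
    """Line network per ALF type at a requested length density.

    ``density_per_type`` maps ALF type -> km of line per km^2 of extent.
    The realized total length per type lands within 10% of the request
    (random segments hit it exactly; partition grids are topped up with a
    short filler segment).
    """
    if pattern not in ("random_segments", "grid_partition"):
        raise ValueError(f"unknown pattern: {pattern!r}")
    area_km2 = grid.width * grid.height / 1e6
    networks: dict[str, list[LineString]] = {}
    rng = np.random.default_rng(seed)
    for t in ALF_TYPES:
        density = float(density_per_type.get(t, 0.0))
        if density < 0:
            raise ValueError(f"density for '{t}' must be >= 0, got {density}")
        if density == 0:
            networks[t] = []
            continue
        target_m = density * area_km2 * 1000.0
        if pattern == "grid_partition":
            lines = _partition_lines(grid, density, rng)
            realized = sum(ln.length for ln in lines)
            deficit = target_m - realized
            if deficit > 1e-6:
                # top up with horizontal filler lines between the partition
                # rows so the realized density is exact
                n_fill = int(math.ceil(deficit / grid.width))
                for j in range(n_fill):
                    y = grid.y0 + (j + 0.5) * grid.height / (n_fill + 1)
                    length = min(deficit, grid.width)
                    lines.append(LineString([(grid.x0, y), (grid.x0 + length, y)]))
                    deficit -= length
        else:
            lines = _random_segments(grid, target_m, rng)
        networks[t] = lines
    return networks


# ---------------------------------------------------------------------------
# movement simulation
# ---------------------------------------------------------------------------
class OverConstrainedLandscape(RuntimeError):
    """Raised when most steps exhaust their retries against barriers."""


def _zscore_rasters(bundle: LandscapeBundle, betas: dict[str, float]) -> dict[str, np.ndarray]:
    out = {}
    for name in betas:
        arr = bundle.attributes[name]
        sd = float(arr.std())
        out[name] = (arr - arr.mean()) / sd if sd > 0 else np.zeros_like(arr)
    return out


def _month_start(month: int, year: int = 2021) -> np.datetime64:
    return np.datetime64(f"{year:04d}-{month:02d}-01T00:00:00", "s")


def simulate_track(
    bundle: LandscapeBundle,
    params: MovementParams,
    n_fixes: int,
    animal_id: str = "A001",
    species: str = "deer",
    sex: str = "F",
    year: int = 2021,
) -> Track:
    """Simulate a home-ranging GPS track on ``bundle``.

    Each 2-h step proposes a displacement from an OU-style kernel
    (deterministic pull toward the home center plus isotropic Gaussian
    noise), then subjects the proposal to two acceptance gates:

    * habitat: accepted with probability ``min(1, exp(s_new - s_old))``
      where ``s = sum_a habitat_beta[a] * z_a`` and ``z_a`` is the
      z-scored attribute raster at the endpoint — a local step-selection
      rule whose stationary preference increases with the selection score;
    * barriers: if the step segment crosses a line of ALF type ``t`` the
      proposal is rejected with probability ``1 - permeability[t]``.

    Up to ``params.max_retries`` proposals are drawn per step; if all fail
    the animal stays in place for that fix. If more than half of all steps
    exhaust their retries the landscape is over-constrained and an error
    is raised.
    """
    grid = bundle.grid
    cx, cy = params.home_center
    if not bool(grid.contains(cx, cy)):
        raise ValueError(f"home_center {params.home_center} outside grid extent")
    if n_fixes < 2:
        raise ValueError("n_fixes must be >= 2")

    rng = np.random.default_rng(params.seed)
    z = _zscore_rasters(bundle, params.habitat_beta)
    trees = {
        t: STRtree(lines)
        for t, lines in (bundle.alf_lines or {}).items()
        if lines and params.permeability.get(t, 1.0) < 1.0
    }

    phi = 1.0 - math.exp(-params.attraction_rate * params.fix_interval)

    def score(x: float, y: float) -> float:
        row, col = grid.cell_index(x, y)
        return sum(params.habitat_beta[a] * z[a][int(row), int(col)] for a in params.habitat_beta)

    xs = np.empty(n_fixes)
    ys = np.empty(n_fixes)
    xs[0], ys[0] = cx, cy
    s_curr = score(cx, cy)
    stuck = 0
    for i in range(1, n_fixes):
        x0, y0 = xs[i - 1], ys[i - 1]
        accepted = False
        for _ in range(params.max_retries):
            mx = x0 + phi * (cx - x0)
            my = y0 + phi * (cy - y0)
            x1 = mx + params.step_scale * rng.standard_normal()
            y1 = my + params.step_scale * rng.standard_normal()
            if not bool(grid.contains(x1, y1)):
                continue
            if params.habitat_beta:
                s_new = score(x1, y1)
                if rng.random() >= min(1.0, math.exp(min(s_new - s_curr, 50.0))):
                    continue
            else:
                s_new = 0.0
            if trees:
                seg = LineString([(x0, y0), (x1, y1)])
                blocked = False
                for t, tree in trees.items():
                    hits = tree.query(seg, predicate="intersects")
                    if len(hits) and rng.random() >= params.permeability.get(t, 1.0):
                        blocked = True
                        break
                if blocked:
                    continue
            xs[i], ys[i] = x1, y1
            s_curr = s_new
            accepted = True
            break
        if not accepted:
            xs[i], ys[i] = x0, y0
            stuck += 1
    if stuck > 0.5 * (n_fixes - 1):
        raise OverConstrainedLandscape(
            f"{stuck}/{n_fixes - 1} steps exhausted all retries; "
            "landscape barriers are over-constrained for these parameters"
        )

    t0 = _month_start(params.season_month, year)
    step = np.timedelta64(int(params.fix_interval * 3600), "s")
    timestamps = t0 + step * np.arange(n_fixes)
    return Track(animal_id=animal_id, species=species, sex=sex, timestamps=timestamps, x=xs, y=ys)
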