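"""Fold construction: individual-season-year subsets of GPS fixes.

A *fold* is the unit of analysis: all of one animal's fixes in one
season window (February = winter, July = summer) of one year. Folds are
filtered on data-sufficiency rules and weighted by how well-informed
they are (number of fixes times number of tracking days, normalized to
mean 1 within a model dataset).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np

from .synthetic import Track

SEASON_MONTHS = {"winter": 2, "summer": 7}

MIN_POINTS = 20
MIN_DAYS = 2
MIN_AREA_M2 = 900.0  # one 30-m raster cell


@dataclass
class Fold:
    animal_id: str
    species: str
    sex: str
    season: str
    year: int
    timestamps: np.ndarray  # datetime64[s]
    x: np.ndarray
    y: np.ndarray
    weight: float | None = None

    @property
    def fold_id(self) -> str:
        return f"{self.animal_id}_{self.season}_{self.year}"

    @property
    def n_points(self) -> int:
        return len(self.timestamps)

    @property
    def n_days(self) -> int:
        """Distinct calendar dates with at least one fix."""
        return len(np.unique(self.timestamps.astype("datetime64[D]")))

    def points(self) -> np.ndarray:
        return np.column_stack([self.x, self.y])


@dataclass(frozen=True)
class FilterDecision:
    fold_id: str
    kept: bool
    reason: str  # too_few_points | one_day | area_too_small | outside_extent | ok

    def __post_init__(self) -> None:
        if (self.reason == "ok") != self.kept:
            raise ValueError("reason must be 'ok' iff kept")


def split_folds(
    tracks: Iterable[Track],
    season_months: dict[str, int] | None = None,
    years: Iterable[int] | None = None,
) -> list[Fold]:
    """One fold per (animal, season, year) with at least one fix in the window.

    Fixes outside the season months are discarded; every retained fix
    lands in exactly one fold.
    """
    season_months = season_months or SEASON_MONTHS
    tracks = list(tracks)
    if not tracks:
        raise ValueError("empty track set")
    years = set(years) if years is not None else None
    folds: list[Fold] = []
    for track in tracks:
        months = track.timestamps.astype("datetime64[M]")
        fix_year = months.astype("datetime64[Y]").astype(int) + 1970
        fix_month = months.astype(int) % 12 + 1
        for season, month in season_months.items():
            for year in np.unique(fix_year):
                if years is not None and int(year) not in years:
                    continue
                mask = (fix_year == year) & (fix_month == month)
                if not mask.any():
                    continue
                folds.append(
                    Fold(
                        animal_id=track.animal_id,
                        species=track.species,
                        sex=track.sex,
                        season=season,
                        year=int(year),
                        timestamps=track.timestamps[mask],
                        x=track.x[mask],
                        y=track.y[mask],
                    )
                )
    return folds


def filter_fold(
    fold: Fold,
    od_area_m2: float | None = None,
    study_extent=None,
    od_centroid: tuple[float, float] | None = None,
) -> FilterDecision:
    """Apply the inclusion rules in order and report the first failure.

    Point-count and day-count rules need only the fixes; the area and
    extent rules need the fold's occurrence distribution and are skipped
    when ``od_area_m2`` / ``od_centroid`` are not supplied (the caller
    applies them after OD estimation).
    """
    if fold.n_points < MIN_POINTS:
        return FilterDecision(fold.fold_id, False, "too_few_points")
    if fold.n_days < MIN_DAYS:
        return FilterDecision(fold.fold_id, False, "one_day")
    if od_area_m2 is not None and od_area_m2 < MIN_AREA_M2:
        return FilterDecision(fold.fold_id, False, "area_too_small")
    if study_extent is not None and od_centroid is not None:
        from shapely.geometry import Point

        if not study_extent.covers(Point(od_centroid)):
            return FilterDecision(fold.fold_id, False, "outside_extent")
    return FilterDecision(fold.fold_id, True, "ok")


def fold_weight(folds: list[Fold]) -> list[Fold]:
    """Set each fold's weight to (n_points * n_days) / mean over the set.

    Normalizing by the mean keeps relative weights intact and makes the
    average observation carry weight 1, so the weighted-likelihood scale
    is comparable across species-season datasets.
    """
    if not folds:
        raise ValueError("empty fold list")
    products = np.array([f.n_points * f.n_days for f in folds], dtype=float)
    mean = products.mean()
    for f, p in zip(folds, products):
        f.weight = float(p / mean)
    return folds
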