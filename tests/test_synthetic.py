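"""Generators: determinism, field structure, line density, walk behavior."""

import numpy as np
import pytest
from scipy.optimize import curve_fit
from shapely.geometry import LineString

from alfrange import (
    GridSpec,
    MovementParams,
    gen_alf_lines,
    gen_landscape,
    simulate_track,
)
from alfrange.synthetic import ALF_TYPES, OverConstrainedLandscape, gaussian_random_field


def total_length_km(lines):
    return sum(ln.length for ln in lines) / 1000.0


class TestLandscape:
    def test_same_seed_identical(self, grid100):
        a = gen_landscape(grid100, seed=7, season_month=2)
        b = gen_landscape(grid100, seed=7, season_month=2)
        for name in a.attributes:
            np.testing.assert_array_equal(a.attributes[name], b.attributes[name])

    def test_different_seed_differs(self, grid100):
        a = gen_landscape(grid100, seed=7)
        b = gen_landscape(grid100, seed=8)
        assert not np.array_equal(a.attributes["forage"], b.attributes["forage"])

    def test_invariants(self, winter_bundle):
        assert (winter_bundle.attributes["roughness"] >= 0).all()
        for name, arr in winter_bundle.attributes.items():
            assert np.isfinite(arr).all(), name
        for arr in winter_bundle.alf.values():
            assert set(np.unique(arr)) <= {0, 1}

    def test_summer_snow_is_zero(self, grid100):
        b = gen_landscape(grid100, seed=3, season_month=7)
        assert np.all(b.attributes["snow"] == 0)

    def test_winter_snow_nonzero(self, winter_bundle):
        assert winter_bundle.attributes["snow"].std() > 0

    def test_too_small_grid_rejected(self):
        with pytest.raises(ValueError, match="too small"):
            gen_landscape(GridSpec(0, 0, 30, 40, 40), seed=0)

    def test_long_correlation_gives_near_constant_field(self):
        # correlation length far beyond the window: within-realization
        # variance collapses even though the marginal variance is 1
        z = gaussian_random_field(80, 80, corr_cells=2000.0, rng=np.random.default_rng(5))
        assert z.var() < 0.05

    def test_semivariogram_range_matches_spec(self):
        """Empirical semivariogram range recovers the requested correlation length."""
        corr = 10.0  # cells
        z = gaussian_random_field(100, 100, corr, rng=np.random.default_rng(11))
        rng = np.random.default_rng(0)
        ii = rng.integers(0, 100, size=(40000, 2))
        jj = rng.integers(0, 100, size=(40000, 2))
        h = np.hypot(*(ii - jj).T)
        sq = 0.5 * (z[ii[:, 0], ii[:, 1]] - z[jj[:, 0], jj[:, 1]]) ** 2
        keep = (h > 0) & (h < 4 * corr)
        bins = np.arange(1, 4 * corr, 2.0)
        idx = np.digitize(h[keep], bins)
        gamma = np.array([sq[keep][idx == i].mean() for i in range(1, len(bins))])
        centers = (bins[:-1] + bins[1:]) / 2

        def model(hh, sill, ell):
            return sill * (1 - np.exp(-(hh**2) / (2 * ell**2)))

        (sill, ell), _ = curve_fit(model, centers, gamma, p0=(1.0, corr))
        assert abs(ell - corr) / corr < 0.25


class TestAlfLines:
    def test_zero_density_empty(self, grid100):
        nets = gen_alf_lines(grid100, {t: 0.0 for t in ALF_TYPES}, seed=1)
        assert all(nets[t] == [] for t in ALF_TYPES)

    def test_negative_density_rejected(self, grid100):
        with pytest.raises(ValueError, match=">= 0"):
            gen_alf_lines(grid100, {"fence": -1.0}, seed=1)

    @pytest.mark.parametrize("density", [0.5, 1.0, 2.0])
    @pytest.mark.parametrize("pattern", ["random_segments", "grid_partition"])
    def test_realized_density_within_ten_percent(self, grid100, density, pattern):
        nets = gen_alf_lines(grid100, {"fence": density}, pattern, seed=3)
        area_km2 = grid100.width * grid100.height / 1e6
        realized = total_length_km(nets["fence"]) / area_km2
        assert abs(realized - density) / density <= 0.10

    def test_partition_total_length_analytic(self, grid100):
        # spacing s on a square of side L: interior lines total ~ 2 L^2 / s
        s_km = 1.0
        density = 2.0 / s_km
        nets = gen_alf_lines(grid100, {"fence": density}, "grid_partition", seed=2)
        L = grid100.width / 1000.0
        expected = 2 * L**2 / s_km
        assert abs(total_length_km(nets["fence"]) - expected) / expected <= 0.10

    def test_deterministic(self, grid100):
        a = gen_alf_lines(grid100, {"paved": 1.0}, seed=9)
        b = gen_alf_lines(grid100, {"paved": 1.0}, seed=9)
        assert [ln.wkt for ln in a["paved"]] == [ln.wkt for ln in b["paved"]]


class TestSimulateTrack:
    def test_deterministic(self, winter_bundle):
        p = MovementParams(home_center=(1500, 1500), seed=5, season_month=2)
        a = simulate_track(winter_bundle, p, 50)
        b = simulate_track(winter_bundle, p, 50)
        np.testing.assert_array_equal(a.x, b.x)
        np.testing.assert_array_equal(a.timestamps, b.timestamps)

    def test_center_outside_grid_rejected(self, winter_bundle):
        with pytest.raises(ValueError, match="outside grid"):
            simulate_track(
                winter_bundle, MovementParams(home_center=(-10, 0), seed=1), 10
            )

    def test_timestamps_follow_fix_interval(self, winter_bundle):
        p = MovementParams(home_center=(1500, 1500), seed=2, season_month=2)
        t = simulate_track(winter_bundle, p, 30)
        deltas = np.diff(t.timestamps.astype("int64"))
        assert (deltas == 7200).all()

    def test_impermeable_ring_contains_all_fixes(self, grid100):
        """A walker sealed inside a permeability-0 fence ring never escapes."""
        bundle = gen_landscape(grid100, seed=6)
        half = 600.0
        cx = cy = 1500.0
        ring = LineString(
            [
                (cx - half, cy - half),
                (cx + half, cy - half),
                (cx + half, cy + half),
                (cx - half, cy + half),
                (cx - half, cy - half),
            ]
        )
        bundle.alf_lines = {"fence": [ring]}
        p = MovementParams(
            home_center=(cx, cy), permeability={"fence": 0.0}, seed=17
        )
        t = simulate_track(bundle, p, 300)
        assert np.all(np.abs(t.x - cx) <= half)
        assert np.all(np.abs(t.y - cy) <= half)

    def test_attracted_walk_is_stationary(self, grid100):
        """Displacement variance stabilizes: first and second half agree."""
        bundle = gen_landscape(grid100, seed=8)
        p = MovementParams(
            home_center=(1500, 1500), step_scale=120.0, attraction_rate=0.3, seed=21
        )
        t = simulate_track(bundle, p, 10_000)
        d2 = (t.x - 1500) ** 2 + (t.y - 1500) ** 2
        v1, v2 = d2[: len(d2) // 2].mean(), d2[len(d2) // 2 :].mean()
        assert 0.7 < v1 / v2 < 1.4
        # bounded: OU stationary variance per axis = s^2 / (1 - (1-phi)^2)
        phi = 1 - np.exp(-0.3 * 2.0)
        expected = 2 * 120.0**2 / (1 - (1 - phi) ** 2)
        assert d2.mean() < 3 * expected

    def test_positive_forage_beta_selects_forage(self, grid100):
        bundle = gen_landscape(grid100, seed=9)
        p = MovementParams(
            home_center=(1500, 1500), habitat_beta={"forage": 2.0}, seed=33
        )
        t = simulate_track(bundle, p, 600)
        rows, cols = grid100.cell_index(t.x, t.y)
        used = bundle.attributes["forage"][rows, cols].mean()
        assert used > bundle.attributes["forage"].mean()

    def test_overconstrained_landscape_raises(self, grid100):
        # sealed in a ring much tighter than the step kernel: nearly every
        # proposal crosses, so most steps exhaust their retries
        bundle = gen_landscape(grid100, seed=10)
        cx = cy = 1500.0
        half = 30.0
        ring = LineString(
            [
                (cx - half, cy - half),
                (cx + half, cy - half),
                (cx + half, cy + half),
                (cx - half, cy + half),
                (cx - half, cy - half),
            ]
        )
        bundle.alf_lines = {"fence": [ring]}
        p = MovementParams(
            home_center=(cx, cy), step_scale=400.0, permeability={"fence": 0.0}, seed=3
        )
        with pytest.raises(OverConstrainedLandscape):
            simulate_track(bundle, p, 100)
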