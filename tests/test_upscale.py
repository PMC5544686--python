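"""Grid geometry, distance-to-land, and global integration."""

import numpy as np
import pytest
from shapely.geometry import LineString, box

from aeromarine.core_io import PROKARYOTE
from aeromarine.fitstats import DecayFit
from aeromarine.upscale import (EARTH_RADIUS_M, build_grid, cell_areas,
                                distance_to_land, global_fluxes, global_load,
                                interpolate_field)


def load_fit(a, b):
    return DecayFit(amplitude=a, rate=b, r_squared=1.0, aic=0.0, n=8,
                    fit_target="load")


@pytest.fixture(scope="module")
def half_plane_grid():
    """Ocean east of a meridional continent, 1 degree cells, 40S-40N."""
    coast = box(-25.0, -65.0, 0.0, 65.0)
    return build_grid(1.0, lat_bounds=(-40.0, 40.0), lon_bounds=(-25.0, 40.0),
                      coastline=coast)


class TestGridGeometry:
    def test_global_area_closes_to_sphere(self):
        grid = build_grid(1.0, lat_bounds=(-90.0, 90.0))
        total = grid.cell_area.sum()
        sphere = 4.0 * np.pi * EARTH_RADIUS_M ** 2
        assert abs(total / sphere - 1.0) < 1e-9

    def test_equatorial_cell_area(self):
        area = cell_areas(np.array([0.0, 1.0]), np.array([0.0, 1.0]))
        assert area[0, 0] == pytest.approx(1.236e10, rel=0.001)

    def test_area_decreases_toward_poles(self):
        grid = build_grid(2.0, lat_bounds=(-90.0, 90.0))
        band = grid.cell_area[:, 0]
        north = band[band.size // 2:]
        assert (np.diff(north) < 0).all()

    def test_resolution_must_divide_domain(self):
        with pytest.raises(ValueError):
            build_grid(3.0, lat_bounds=(-40.0, 40.0))
        with pytest.raises(ValueError):
            build_grid(1.0, lat_bounds=(40.0, -40.0))

    def test_land_mask_covers_continent(self, half_plane_grid):
        g = half_plane_grid
        j_land = np.searchsorted(g.lon_edges, -10.0)
        j_ocean = np.searchsorted(g.lon_edges, 20.0)
        assert g.land_mask[:, j_land].all()
        assert not g.land_mask[:, j_ocean].any()
        assert np.isnan(g.distance_to_land[g.land_mask]).all()


class TestDistanceToLand:
    def test_point_on_coast_is_zero(self):
        # sampled-coastline distance: error bounded by half the sampling step
        coast = LineString([(0.0, -10.0), (0.0, 10.0)])
        assert distance_to_land(5.0, 0.0, coast,
                                spacing_km=0.1) == pytest.approx(0.0,
                                                                 abs=0.1)

    def test_one_degree_offshore_at_equator(self):
        coast = LineString([(0.0, -10.0), (0.0, 10.0)])
        assert distance_to_land(0.0, 1.0, coast) == pytest.approx(111.2,
                                                                  rel=0.001)

    def test_monotone_along_bearing(self):
        coast = LineString([(0.0, -10.0), (0.0, 10.0)])
        d = distance_to_land(np.zeros(5), np.array([1.0, 2.0, 5.0, 10., 20.]),
                             coast)
        assert (np.diff(d) > 0).all()


class TestGlobalLoad:
    def test_uniform_load_equals_area_product(self, half_plane_grid):
        g = half_plane_grid
        fit = load_fit(3.0e6, 0.0)  # b = 0: uniform 3e6 cells/m^2
        expected = 3.0e6 * g.cell_area[g.ocean].sum()
        assert global_load(g, fit) == pytest.approx(expected, rel=1e-12)

    def test_half_plane_matches_strip_integral(self, half_plane_grid):
        # closed form for an exponential profile off a straight coast:
        # integral a exp(-b x) dx = a/b per metre of coastline
        a, b = 25454.0 * 817.0, 0.0037
        numeric = global_load(half_plane_grid, load_fit(a, b))
        coast_length = EARTH_RADIUS_M * np.radians(80.0)
        analytic = a / (b / 1000.0) * coast_length
        assert numeric == pytest.approx(analytic, rel=0.02)

    def test_additive_over_disjoint_regions(self):
        coast = box(-20.0, -65.0, 0.0, 65.0)
        fit = load_fit(1e6, 0.002)
        whole = build_grid(1.0, (-40.0, 40.0), (0.0, 40.0), coast)
        south = build_grid(1.0, (-40.0, 0.0), (0.0, 40.0), coast)
        north = build_grid(1.0, (0.0, 40.0), (0.0, 40.0), coast)
        assert global_load(whole, fit) == pytest.approx(
            global_load(south, fit) + global_load(north, fit), rel=1e-9)

    def test_requires_distance_field(self):
        grid = build_grid(10.0, (-40.0, 40.0))
        with pytest.raises(ValueError, match="distance"):
            global_load(grid, load_fit(1.0, 0.001))


@pytest.fixture(scope="module")
def uniform_world():
    grid = build_grid(10.0, (-40.0, 40.0), (0.0, 40.0))
    shp = grid.cell_area.shape
    meteo = {"u10": np.full(shp, 8.0), "T": np.full(shp, 298.15),
             "RH": np.full(shp, 80.0), "P": np.full(shp, 101325.0)}
    return grid, meteo


class TestGlobalFluxes:
    def test_uniform_fields_analytic(self, uniform_world):
        from aeromarine.core_io import MeteoState
        from aeromarine.exchange import SECONDS_PER_YEAR
        from aeromarine.microphysics import (deposition_velocity,
                                             spray_volume_velocity)
        grid, meteo = uniform_world
        c_air = np.full(grid.cell_area.shape, 6.7e3)
        est = global_fluxes(grid, c_air, meteo, (0.5e12, 1.5e12), PROKARYOTE)
        m = MeteoState(8.0, 298.15, 80.0, 101325.0)
        area = grid.cell_area.sum()
        v_d = deposition_velocity(PROKARYOTE, m)
        assert est.gross_deposition["prokaryote"] == pytest.approx(
            v_d * 6.7e3 * area * SECONDS_PER_YEAR, rel=1e-9)
        v_s = spray_volume_velocity(m)
        assert est.gross_emission_max["prokaryote"] == pytest.approx(
            v_s * 1.5e12 * area * SECONDS_PER_YEAR, rel=1e-9)

    def test_emission_ratio_follows_water_abundance(self, uniform_world):
        grid, meteo = uniform_world
        c_air = np.full(grid.cell_area.shape, 1e3)
        est = global_fluxes(grid, c_air, meteo, (0.5e12, 1.5e12), PROKARYOTE)
        ratio = (est.gross_emission_max["prokaryote"]
                 / est.gross_emission_min["prokaryote"])
        assert ratio == pytest.approx(3.0, rel=1e-12)

    def test_net_is_deposition_minus_max_emission(self, uniform_world):
        grid, meteo = uniform_world
        c_air = np.full(grid.cell_area.shape, 6.7e3)
        est = global_fluxes(grid, c_air, meteo, (0.5e12, 1.5e12), PROKARYOTE)
        assert est.net_deposition["prokaryote"] == pytest.approx(
            est.gross_deposition["prokaryote"]
            - est.gross_emission_max["prokaryote"], rel=1e-12)

    def test_misaligned_fields_rejected(self, uniform_world):
        grid, meteo = uniform_world
        with pytest.raises(ValueError):
            global_fluxes(grid, np.zeros((2, 2)), meteo, (1e12, 1e12),
                          PROKARYOTE)


class TestInterpolation:
    def test_constant_field_maps_to_constant(self):
        src = build_grid(1.0, (-40.0, 40.0), (0.0, 40.0))
        dst = build_grid(2.5, (-40.0, 40.0), (0.0, 40.0))
        out = interpolate_field(np.full(src.cell_area.shape, 4.2), src, dst)
        assert np.allclose(out, 4.2)

    def test_linear_in_latitude_exact_inside(self):
        src = build_grid(1.0, (-40.0, 40.0), (0.0, 40.0))
        dst = build_grid(2.0, (-30.0, 30.0), (10.0, 30.0))
        field = np.broadcast_to(src.lat_centers[:, None],
                                src.cell_area.shape).copy()
        out = interpolate_field(field, src, dst)
        expected = np.broadcast_to(dst.lat_centers[:, None], out.shape)
        assert np.allclose(out, expected, atol=1e-9)

    def test_disjoint_domains_rejected(self):
        src = build_grid(1.0, (-40.0, 0.0), (0.0, 20.0))
        dst = build_grid(1.0, (20.0, 40.0), (100.0, 120.0))
        with pytest.raises(ValueError):
            interpolate_field(np.zeros(src.cell_area.shape), src, dst)
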