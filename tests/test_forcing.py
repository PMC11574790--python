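"""Forcing geometry: series I/O, interpolation, hypsometry, coastline retreat."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from islandgame import (
    AreaSeries,
    ElevationGrid,
    ModelParams,
    SeaLevelCurve,
    annual_territories,
    area_history,
    cone_island,
    interpolate_series,
    max_coastline_retreat,
    read_area_series,
    read_esri_ascii,
    relative_area_stats,
    subaerial_area,
    write_esri_ascii,
)


@pytest.fixture
def steep_cone():
    """400 m apex, 40 m/km slope: datum radius 10 km, A(0) = pi*100 km^2."""
    return cone_island(apex_m=400.0, slope_m_per_km=40.0, extent_km=30.0, cell_km=0.5)


class TestAreaSeriesIO:
    def test_round_trip(self, tmp_path):
        path = tmp_path / "areas.csv"
        path.write_text("time_ky_bp,area_km2\n26,2958\n0,1852\n")
        s = read_area_series(path)
        assert len(s) == 2
        assert s.times_ybp[0] == 26000.0
        assert s.areas_km2[-1] == 1852.0

    def test_unsorted_rows_sorted_on_read(self, tmp_path):
        path = tmp_path / "areas.csv"
        path.write_text("time_ky_bp,area_km2\n0,1852\n26,2958\n10,2000\n")
        s = read_area_series(path)
        assert np.all(np.diff(s.times_ybp) < 0)

    def test_negative_area_names_row(self, tmp_path):
        path = tmp_path / "areas.csv"
        path.write_text("time_ky_bp,area_km2\n26,2958\n10,-5\n0,1852\n")
        with pytest.raises(ValueError, match="row 1"):
            read_area_series(path)

    def test_non_numeric_cell_names_row(self, tmp_path):
        path = tmp_path / "areas.csv"
        path.write_text("time_ky_bp,area_km2\n26,2958\n0,oops\n")
        with pytest.raises(ValueError, match="row 1"):
            read_area_series(path)

    def test_missing_column(self, tmp_path):
        path = tmp_path / "areas.csv"
        path.write_text("time,area\n26,2958\n")
        with pytest.raises(ValueError, match="time_ky_bp"):
            read_area_series(path)


class TestInterpolation:
    def test_endpoints_exact_and_midpoint_mean(self):
        s = AreaSeries(times_ybp=np.array([2000.0, 0.0]), areas_km2=np.array([100.0, 300.0]))
        out = interpolate_series(s, 1000.0)
        assert out.times_ybp[0] == 2000.0 and out.times_ybp[-1] == 0.0
        assert out.areas_km2[1] == pytest.approx(200.0)

    @given(st.integers(2, 6), st.integers(0, 2**31 - 1))
    @settings(max_examples=30, deadline=None)
    def test_refinement_consistency(self, n_pts, seed):
        rng = np.random.default_rng(seed)
        times = np.sort(rng.choice(np.arange(1, 50) * 1000.0, size=n_pts, replace=False))[::-1]
        areas = rng.uniform(10, 1000, size=n_pts)
        s = AreaSeries(times_ybp=times, areas_km2=areas)
        coarse = interpolate_series(s, 500.0)
        fine = interpolate_series(s, 250.0)
        shared = np.intersect1d(coarse.times_ybp, fine.times_ybp)
        a_c = dict(zip(coarse.times_ybp, coarse.areas_km2))
        a_f = dict(zip(fine.times_ybp, fine.areas_km2))
        for t in shared:
            assert a_c[t] == pytest.approx(a_f[t], rel=1e-12, abs=1e-12)

    def test_territory_conversion_commutes_with_area_scaling(self, params):
        s = AreaSeries(times_ybp=np.array([3000.0, 1000.0, 0.0]),
                       areas_km2=np.array([50.0, 200.0, 120.0]))
        k1 = annual_territories(s, params).K
        s2 = AreaSeries(times_ybp=s.times_ybp, areas_km2=2.0 * s.areas_km2)
        k2 = annual_territories(s2, params).K
        assert np.allclose(k2, 2.0 * k1, rtol=1e-14)


class TestSubaerialArea:
    def test_cone_matches_closed_form_at_datum(self, steep_cone):
        got = subaerial_area(steep_cone, 0.0)
        expected = math.pi * 10.0**2
        ring = 2 * math.pi * 10.0 * 0.5  # one cell-ring of discretisation slack
        assert abs(got - expected) < ring

    def test_cone_matches_closed_form_at_lowstand(self, steep_cone):
        got = subaerial_area(steep_cone, -135.0)
        r = (400.0 + 135.0) / 40.0
        assert abs(got - math.pi * r**2) < 2 * math.pi * r * 0.5

    def test_sea_above_apex_drowns_island(self, steep_cone):
        assert subaerial_area(steep_cone, 401.0) == 0.0

    def test_cells_at_datum_are_sea(self):
        grid = ElevationGrid(elevations=np.array([[0.0, 1.0], [-1.0, 5.0]]), cell_size=1.0)
        assert subaerial_area(grid, 0.0) == pytest.approx(2.0)

    def test_monotone_in_sea_level(self, steep_cone):
        levels = np.linspace(-140, 400, 30)
        areas = [subaerial_area(steep_cone, s) for s in levels]
        assert np.all(np.diff(areas) <= 0)

    def test_converges_with_resolution(self):
        expected = math.pi * 10.0**2
        errs = []
        for cell in (1.0, 0.25):
            g = cone_island(400.0, 40.0, extent_km=24.0, cell_km=cell)
            errs.append(abs(subaerial_area(g, 0.0) - expected))
        assert errs[1] < errs[0]

    def test_geographic_grid_scales_by_cos_latitude(self):
        z = np.full((4, 4), 10.0)
        flat = ElevationGrid(elevations=z, cell_size=0.1, unit="deg", yll=59.8)
        equator = ElevationGrid(elevations=z, cell_size=0.1, unit="deg", yll=-0.2)
        a60 = subaerial_area(flat, 0.0)
        a0 = subaerial_area(equator, 0.0)
        assert a60 / a0 == pytest.approx(math.cos(math.radians(60.0)), rel=0.01)


class TestAreaHistory:
    def test_constant_curve_constant_series(self, steep_cone):
        curve = SeaLevelCurve(times_ybp=np.array([2000.0, 1000.0, 0.0]),
                              levels_m=np.array([-20.0, -20.0, -20.0]))
        s = area_history(steep_cone, curve)
        assert np.allclose(s.areas_km2, s.areas_km2[0])

    def test_falling_sea_grows_island(self, steep_cone):
        curve = SeaLevelCurve(times_ybp=np.arange(10)[::-1] * 1000.0,
                              levels_m=np.linspace(0, -100, 10))
        s = area_history(steep_cone, curve)
        assert np.all(np.diff(s.areas_km2) >= 0)


class TestRelativeAreaStats:
    def test_flat_series(self):
        t = np.arange(0, 31)[::-1] * 1000.0
        s = AreaSeries(times_ybp=t, areas_km2=np.full(t.size, 500.0))
        stats = relative_area_stats(s)
        assert np.allclose(stats.pct_of_lgm_max, 100.0)
        assert np.allclose(stats.pct_change_per_ky.dropna(), 0.0)

    def test_ten_percent_drop_rate(self):
        t = np.arange(0, 31)[::-1] * 1000.0
        a = np.full(t.size, 100.0)
        a[-1] = 90.0  # last ky: 100 -> 90
        s = AreaSeries(times_ybp=t, areas_km2=a)
        stats = relative_area_stats(s)
        assert stats.pct_change_per_ky.iloc[-1] == pytest.approx(-10.0)

    def test_requires_lgm_coverage(self):
        s = AreaSeries(times_ybp=np.array([10000.0, 0.0]), areas_km2=np.array([1.0, 1.0]))
        with pytest.raises(ValueError, match="LGM"):
            relative_area_stats(s)


class TestCoastlineRetreat:
    def test_no_flooding_zero_retreat(self):
        # binary plateau: nothing lies between the two stands, so nothing floods
        z = np.where(np.arange(100).reshape(10, 10) % 2 == 0, 50.0, -50.0)
        g = ElevationGrid(elevations=z, cell_size=0.5)
        assert max_coastline_retreat(g, -10.0, 0.0) == 0.0

    def test_planar_beach_closed_form(self):
        # uniform 20 m/km slope dipping east; 40 m rise => 2 km retreat
        ncols, cell = 120, 0.25
        x = (np.arange(ncols) + 0.5) * cell
        z = np.tile(100.0 - 20.0 * x, (20, 1))
        g = ElevationGrid(elevations=z, cell_size=cell)
        got = max_coastline_retreat(g, -40.0, 0.0)
        assert got == pytest.approx(2000.0, abs=cell * 1000.0)

    def test_cone_deglacial_retreat(self):
        g = cone_island(400.0, 40.0, extent_km=30.0, cell_km=0.25)
        got = max_coastline_retreat(g, -135.0, 0.0)
        assert got == pytest.approx(3375.0, abs=250.0)

    def test_transgression_required(self):
        g = cone_island(400.0, 40.0, extent_km=24.0, cell_km=0.5)
        with pytest.raises(ValueError):
            max_coastline_retreat(g, 0.0, -10.0)


class TestEsriAscii:
    def test_round_trip(self, tmp_path):
        g = cone_island(400.0, 40.0, extent_km=10.0, cell_km=1.0)
        path = tmp_path / "dem.asc"
        write_esri_ascii(g, path)
        back = read_esri_ascii(path)
        assert back.shape == g.shape
        assert back.cell_size == g.cell_size
        assert np.allclose(back.elevations, g.elevations, atol=5e-3)

    def test_malformed_header_rejected(self, tmp_path):
        path = tmp_path / "bad.asc"
        path.write_text("ncols 2\n1 2\n3 4\n")
        with pytest.raises(ValueError, match="header"):
            read_esri_ascii(path)
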