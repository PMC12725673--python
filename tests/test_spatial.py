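"""Rasterization, normalization, centroids, geodesic distances, raster I/O."""

import numpy as np
import pytest
from shapely.geometry import Point, Polygon

from vcclek.geodesy import distance_to_polyline_km, geodesic_distance_m
from vcclek.spatial_analysis import (
    FishingGround,
    GridSpec,
    GridSurface,
    centroid,
    core_fishing_cells,
    decadal_distance_summary,
    distance_to_port,
    load_fishing_grounds,
    normalize_surface,
    rasterize_effort,
    read_ascii_grid,
    vcc_surface,
    write_ascii_grid,
    write_fishing_grounds,
)
from vcclek.survey_model import Port, PortRegistry

#: Distances (m) computed with geosphere::distGeo (WGS84), the reference
#: routine of the original spatial workflow.
GEOSPHERE_ORACLE = [
    ((0.0, 0.0), (1.0, 0.0), 111319.491),
    ((-80.9, -0.6), (-80.4, -0.55), 55930.885),
    ((-81.5, -2.2), (-80.3, -2.05), 134518.578),
    ((-82.0, 1.0), (-80.45, 0.6), 178107.382),
]


def _square(x0, y0, side=1.0):
    return Polygon([(x0, y0), (x0 + side, y0),
                    (x0 + side, y0 + side), (x0, y0 + side)])


def _ground(poly, fid="f0", decade="1980s", port="p0", vcc=None):
    return FishingGround(fid, decade, poly, port, vcc)


class TestRasterizeEffort:
    def test_single_polygon_is_an_indicator(self):
        spec = GridSpec.from_bounds(0, 0, 1, 1, cell_size=0.1)
        surf = rasterize_effort([_ground(_square(0, 0))], spec)
        assert set(np.unique(surf.values)) <= {0.0, 1.0}
        assert surf.values.sum() == 100  # ten by ten interior centres

    def test_identical_polygons_add(self):
        spec = GridSpec.from_bounds(0, 0, 1, 1, cell_size=0.1)
        surf = rasterize_effort([_ground(_square(0, 0), "a"),
                                 _ground(_square(0, 0), "b")], spec)
        assert set(np.unique(surf.values)) <= {0.0, 2.0}

    def test_matches_brute_force_point_in_polygon_oracle(self):
        """Cell counts equal an exhaustive centre-by-centre containment check
        for a field of random convex polygons on a 50x50 grid."""
        rng = np.random.default_rng(11)
        spec = GridSpec(origin_lon=0.0, origin_lat=5.0, cell_size=0.1,
                        n_cols=50, n_rows=50)
        grounds = []
        for i in range(25):
            cx, cy = rng.uniform(0.5, 4.5, 2)
            pts = np.column_stack([cx + rng.uniform(-0.45, 0.45, 8),
                                   cy + rng.uniform(-0.45, 0.45, 8)])
            hull = Polygon(pts).convex_hull
            grounds.append(_ground(hull, f"f{i}"))
        surf = rasterize_effort(grounds, spec)

        xs, ys = spec.col_centers(), spec.row_centers()
        oracle = np.zeros((50, 50))
        for r in range(50):
            for c in range(50):
                p = Point(xs[c], ys[r])
                oracle[r, c] = sum(g.polygon.contains(p) for g in grounds)
        np.testing.assert_array_equal(surf.values, oracle)
        # conservation: total = sum over polygons of contained centres
        assert surf.values.sum() == oracle.sum()

    def test_permutation_invariance(self):
        rng = np.random.default_rng(3)
        spec = GridSpec.from_bounds(0, 0, 2, 2, cell_size=0.1)
        grounds = [_ground(_square(rng.uniform(0, 1), rng.uniform(0, 1),
                                   rng.uniform(0.2, 0.9)), f"f{i}")
                   for i in range(8)]
        a = rasterize_effort(grounds, spec)
        b = rasterize_effort(grounds[::-1], spec)
        np.testing.assert_array_equal(a.values, b.values)

    def test_polygon_outside_grid_names_the_fisher(self):
        spec = GridSpec.from_bounds(0, 0, 1, 1, cell_size=0.1)
        with pytest.raises(ValueError, match="f9"):
            rasterize_effort([_ground(_square(5, 5), "f9")], spec)

    def test_self_intersecting_polygon_repaired(self):
        bowtie = Polygon([(0, 0), (1, 1), (1, 0), (0, 1)])
        g = _ground(bowtie)
        assert g.repaired and g.polygon.is_valid

    def test_finer_grids_converge_to_planar_area(self):
        poly = Polygon([(0.1, 0.1), (1.9, 0.3), (1.5, 1.8), (0.3, 1.6)])
        errors = []
        for cell in (0.2, 0.1, 0.05):
            spec = GridSpec.from_bounds(0, 0, 2, 2, cell_size=cell)
            surf = rasterize_effort([_ground(poly)], spec)
            errors.append(abs(surf.values.sum() * cell**2 - poly.area))
        assert errors[2] < errors[0]


class TestNormalizeSurface:
    def _surf(self, arr, cell=1.0):
        arr = np.asarray(arr, dtype=float)
        spec = GridSpec(0.0, float(arr.shape[0]), cell,
                        arr.shape[1], arr.shape[0])
        return GridSurface(spec, arr)

    def test_unit_divides_by_max(self):
        out = normalize_surface(self._surf([[0, 1], [2, 4]]), "unit")
        np.testing.assert_allclose(out.values, [[0, 0.25], [0.5, 1.0]])
        assert out.values.max() == 1.0

    def test_symmetric4_preserves_sign_and_zero(self):
        out = normalize_surface(self._surf([[-2, 0, 1]]), "symmetric4")
        np.testing.assert_allclose(out.values, [[-4.0, 0.0, 2.0]])
        assert np.abs(out.values).max() == 4.0

    def test_all_zero_surface_flagged_not_scaled(self):
        out = normalize_surface(self._surf([[0.0, 0.0]]), "unit")
        assert out.all_zero
        np.testing.assert_array_equal(out.values, [[0.0, 0.0]])

    @pytest.mark.parametrize("mode", ["unit", "symmetric4"])
    def test_idempotent(self, mode):
        surf = self._surf([[0, 1], [2, 4]]) if mode == "unit" \
            else self._surf([[-2, 0, 1]])
        once = normalize_surface(surf, mode)
        twice = normalize_surface(once, mode)
        np.testing.assert_allclose(twice.values, once.values)

    def test_core_cells_use_share_threshold(self):
        surf = self._surf([[1, 5], [10, 2]])
        mask = core_fishing_cells(surf, threshold=0.6)
        np.testing.assert_array_equal(mask, [[False, False], [True, False]])


class TestVccSurface:
    def test_deposits_vcc_values(self):
        spec = GridSpec.from_bounds(0, 0, 1, 1, cell_size=0.25)
        surf = vcc_surface([_ground(_square(0, 0), vcc=1.5)], spec,
                           normalized=False)
        assert set(np.unique(surf.values)) <= {0.0, 1.5}

    def test_opposite_values_cancel_in_overlap(self):
        spec = GridSpec.from_bounds(0, 0, 2, 1, cell_size=0.25)
        grounds = [_ground(_square(0, 0), "a", vcc=1.0),
                   _ground(_square(0.5, 0), "b", vcc=-1.0)]
        surf = vcc_surface(grounds, spec, normalized=False)
        xs, ys = surf.spec.col_centers(), surf.spec.row_centers()
        overlap = (xs[None, :] > 0.5) & (xs[None, :] < 1.0) \
            & (ys[:, None] > 0) & (ys[:, None] < 1)
        assert np.all(surf.values[overlap] == 0.0)

    def test_unit_vcc_equals_effort_surface(self):
        rng = np.random.default_rng(7)
        spec = GridSpec.from_bounds(0, 0, 3, 3, cell_size=0.1)
        grounds = [_ground(_square(rng.uniform(0, 2), rng.uniform(0, 2),
                                   rng.uniform(0.3, 1.0)), f"f{i}", vcc=1.0)
                   for i in range(10)]
        effort = rasterize_effort(grounds, spec)
        vcc = vcc_surface(grounds, spec, normalized=False)
        np.testing.assert_array_equal(vcc.values, effort.values)

    def test_missing_vcc_value_names_the_fisher(self):
        spec = GridSpec.from_bounds(0, 0, 1, 1, cell_size=0.25)
        with pytest.raises(ValueError, match="f3"):
            vcc_surface([_ground(_square(0, 0), "f3")], spec)


class TestCentroidAndDistance:
    def test_unit_square_centroid(self):
        assert centroid(_square(0, 0)) == pytest.approx((0.5, 0.5))

    def test_right_triangle_centroid(self):
        tri = Polygon([(0, 0), (1, 0), (0, 1)])
        assert centroid(tri) == pytest.approx((1 / 3, 1 / 3))

    def test_irregular_polygon_matches_shoelace_oracle(self):
        coords = [(0.0, 0.0), (2.0, 0.2), (1.8, 1.5), (0.4, 1.9)]
        poly = Polygon(coords)
        x = np.array([c[0] for c in coords]); y = np.array([c[1] for c in coords])
        xn, yn = np.roll(x, -1), np.roll(y, -1)
        cross = x * yn - xn * y
        area = cross.sum() / 2.0
        cx = ((x + xn) * cross).sum() / (6 * area)
        cy = ((y + yn) * cross).sum() / (6 * area)
        assert centroid(poly) == pytest.approx((cx, cy))

    def test_degenerate_polygon_rejected(self):
        with pytest.raises(ValueError):
            centroid(Polygon([(0, 0), (1, 1), (2, 2)]))

    @pytest.mark.parametrize("a, b, expected_m", GEOSPHERE_ORACLE)
    def test_matches_geosphere_reference(self, a, b, expected_m):
        assert geodesic_distance_m(*a, *b) == pytest.approx(expected_m,
                                                            abs=0.01)

    def test_equator_degree_within_half_percent_of_spherical(self):
        d = distance_to_port((0.0, 0.0), (1.0, 0.0))
        assert d == pytest.approx(111.32, abs=0.01)
        assert abs(d - 111.19) / 111.19 < 0.005

    def test_symmetry_and_identity(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            lon1, lon2 = rng.uniform(-179, 179, 2)
            lat1, lat2 = rng.uniform(-85, 85, 2)
            ab = geodesic_distance_m(lon1, lat1, lon2, lat2)
            ba = geodesic_distance_m(lon2, lat2, lon1, lat1)
            assert ab == pytest.approx(ba, abs=1e-6)
        assert geodesic_distance_m(-80.4, -0.95, -80.4, -0.95) == 0.0

    def test_out_of_bounds_coordinates_rejected(self):
        with pytest.raises(ValueError):
            geodesic_distance_m(200.0, 0.0, 0.0, 0.0)

    def test_point_to_polyline_matches_reference(self):
        # geosphere::dist2Line of (-80.9, -0.5) to the meridian segment
        # lon -80.4, lat -2..1 gives 55657.63 m
        d = distance_to_polyline_km(-80.9, -0.5, [(-80.4, -2.0), (-80.4, 1.0)])
        assert d * 1000 == pytest.approx(55657.63, rel=5e-4)


class TestDistanceSummary:
    def _registry(self):
        reg = PortRegistry()
        reg.add(Port("p0", "villageA", -80.4, 0.0))
        return reg

    def test_ground_at_its_port_has_zero_distance(self):
        poly = _square(-80.45, -0.05, 0.1)  # centroid exactly at the port
        df = decadal_distance_summary([_ground(poly)], self._registry())
        row = df[(df.village == "villageA") & (df.decade == "1980s")]
        assert row.mean_km.iloc[0] == pytest.approx(0.0, abs=1e-6)

    def test_known_offsets_reproduce_mean_and_median(self):
        reg = self._registry()
        grounds = []
        expected = []
        for i, off_deg in enumerate([0.2, 0.4, 0.9]):
            poly = _square(-80.4 - off_deg - 0.05, -0.05, 0.1)
            grounds.append(_ground(poly, f"f{i}"))
            expected.append(distance_to_port((-80.4 - off_deg, 0.0),
                                             (-80.4, 0.0)))
        df = decadal_distance_summary(grounds, reg)
        row = df[(df.village == "ALL") & (df.decade == "all")]
        assert row.n.iloc[0] == 3
        assert row.mean_km.iloc[0] == pytest.approx(np.mean(expected))
        assert row.median_km.iloc[0] == pytest.approx(np.median(expected))

    def test_unknown_port_is_an_error(self):
        with pytest.raises(KeyError, match="p9"):
            decadal_distance_summary([_ground(_square(-80.5, 0), port="p9")],
                                     self._registry())


class TestRasterAndGeoJsonIO:
    def test_ascii_grid_round_trip_bit_exact(self, tmp_path):
        rng = np.random.default_rng(0)
        spec = GridSpec(-81.0, 1.0, 0.01, 12, 9)
        surf = GridSurface(spec, rng.normal(size=(9, 12)), kind="vcc")
        path = tmp_path / "surf.asc"
        write_ascii_grid(surf, path)
        back = read_ascii_grid(path, kind="vcc")
        np.testing.assert_array_equal(back.values, surf.values)
        assert back.spec.origin_lon == spec.origin_lon
        assert back.spec.origin_lat == pytest.approx(spec.origin_lat)
        assert (back.spec.n_cols, back.spec.n_rows) == (12, 9)

    def test_geojson_round_trip(self, tmp_path):
        grounds = [_ground(_square(-80.9, -0.4, 0.2), "f1", "1990s",
                           "p0", vcc=1.25)]
        path = tmp_path / "g.geojson"
        write_fishing_grounds(grounds, path)
        back = load_fishing_grounds(path)
        assert len(back) == 1
        assert back[0].fisher_id == "f1"
        assert back[0].decade == "1990s"
        assert back[0].vcc_value == 1.25
        assert back[0].polygon.equals(grounds[0].polygon)
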