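import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from pathsel.features import LinearFeature
from pathsel.grid import Grid, GridError
from pathsel.landscape import (
    DistanceTransformConfig,
    distance_grid,
    log_flatten,
    polyline_stations,
    sample_along_polyline,
    slope_from_dem,
)


def brute_force_distance(features, template, which_type):
    """Independent oracle: min point-to-segment distance over every segment."""
    out = np.full(template.values.shape, np.inf)
    xs, ys = template.cell_centers()
    for f in features:
        if f.feature_type != which_type:
            continue
        for a, b in zip(f.polyline[:-1], f.polyline[1:]):
            ab = b - a
            t = np.clip(((xs - a[0]) * ab[0] + (ys - a[1]) * ab[1]) / (ab @ ab), 0, 1)
            d = np.hypot(xs - (a[0] + t * ab[0]), ys - (a[1] + t * ab[1]))
            out = np.minimum(out, d)
    return out


class TestDistanceGrid:
    def test_vertical_line_analytic(self, template_grid):
        f = [LinearFeature("road", [[0, 0], [0, 600]])]
        d = distance_grid(f, template_grid, "road")
        np.testing.assert_allclose(d.values[:, 0], 15.0)
        np.testing.assert_allclose(d.values[:, 1], 45.0)
        np.testing.assert_allclose(d.values[:, 2], 75.0)

    def test_cell_center_on_vertex_is_zero(self, template_grid):
        f = [LinearFeature("fence", [[15, 585], [300, 585]])]
        d = distance_grid(f, template_grid, "fence")
        assert d.values[0, 0] == 0.0

    def test_crossing_polylines_match_brute_force(self, template_grid, rng):
        feats = [
            LinearFeature("road", rng.uniform(0, 600, (4, 2))),
            LinearFeature("road", rng.uniform(0, 600, (3, 2))),
        ]
        d = distance_grid(feats, template_grid, "road")
        np.testing.assert_allclose(d.values, brute_force_distance(feats, template_grid, "road"), atol=1e-9)

    def test_no_features_gives_missing_with_warning(self, template_grid):
        with pytest.warns(UserWarning, match="no features"):
            d = distance_grid([], template_grid, "rail")
        assert np.all(np.isnan(d.values))


class TestLogFlatten:
    def test_plateau_above_sixty_metres(self, template_grid):
        g = template_grid.like(np.full((20, 20), 600.0))
        g.values[0, 0] = 60.0
        out = log_flatten(g)
        assert out.values[0, 0] == pytest.approx(np.log(61.0))
        assert out.values[5, 5] == pytest.approx(np.log(61.0))

    def test_zero_distance_with_unit_offset(self, template_grid):
        g = template_grid.like(np.zeros((20, 20)))
        assert log_flatten(g).values[0, 0] == 0.0

    def test_negative_distance_rejected(self, template_grid):
        with pytest.raises(ValueError):
            log_flatten(template_grid.like(np.full((20, 20), -1.0)))

    @settings(max_examples=50, deadline=None)
    @given(
        st.lists(
            st.floats(0.0, 59.99).map(lambda v: round(v, 3)),
            min_size=2, max_size=10, unique=True,
        )
    )
    def test_strictly_increasing_below_plateau(self, ds):
        cfg = DistanceTransformConfig()
        g = Grid(np.array([sorted(ds)]), 0, 30, 30)
        out = log_flatten(g, cfg).values[0]
        assert np.all(np.diff(out) > 0)

    def test_missing_propagates(self, template_grid):
        v = np.full((20, 20), 10.0)
        v[3, 3] = np.nan
        out = log_flatten(template_grid.like(v))
        assert np.isnan(out.values[3, 3])


class TestSlope:
    def test_constant_dem_is_flat(self, template_grid):
        s = slope_from_dem(template_grid.like(np.full((20, 20), 100.0)))
        np.testing.assert_allclose(s.values, 0.0)

    def test_inclined_plane_analytic(self, template_grid):
        xs, _ = template_grid.cell_centers()
        s = slope_from_dem(template_grid.like(xs / 30.0))  # 1 m rise per 30 m east
        np.testing.assert_allclose(s.values, np.degrees(np.arctan(1 / 30)), rtol=1e-6)

    def test_pyramid_matches_central_difference_oracle(self, template_grid):
        xs, ys = template_grid.cell_centers()
        dem = template_grid.like(-(np.abs(xs - 300) + np.abs(ys - 300)) / 10)
        s = slope_from_dem(dem)
        z = dem.values
        # independent simple central-difference slope on the interior
        dzdx = (z[1:-1, 2:] - z[1:-1, :-2]) / (2 * 30)
        dzdy = (z[2:, 1:-1] - z[:-2, 1:-1]) / (2 * 30)
        oracle = np.degrees(np.arctan(np.hypot(dzdx, dzdy)))
        # Horn agrees with plain central differences away from the ridgelines
        flat = np.abs(xs[1:-1, 1:-1] - 300) > 45
        np.testing.assert_allclose(s.values[1:-1, 1:-1][flat], oracle[flat], atol=1e-8)

    def test_translation_invariance(self, template_grid, rng):
        dem = template_grid.like(rng.normal(size=(20, 20)) * 50)
        s1 = slope_from_dem(dem)
        s2 = slope_from_dem(template_grid.like(dem.values + 123.4))
        np.testing.assert_allclose(s1.values, s2.values, atol=1e-10)

    def test_too_small_dem_rejected(self):
        with pytest.raises(GridError):
            slope_from_dem(Grid(np.zeros((1, 1)), 0, 30, 30))


class TestSampleAlongPolyline:
    def test_ninety_metre_segment_spacing_ten(self, template_grid):
        # ~90 m west-to-east from the grid edge: ten stations in three columns
        line = np.array([[0.0, 585.0], [89.99, 585.0]])
        vals = sample_along_polyline(template_grid, line, 10.0)
        assert len(vals) == 10
        stations = polyline_stations(line, 10.0)
        cells = {template_grid.world_to_cell(x, y)[1] for x, y in stations}
        assert len(cells) == 3

    def test_constant_grid(self, template_grid):
        g = template_grid.like(np.full((20, 20), 7.0))
        vals = sample_along_polyline(g, [[10, 500], [200, 100], [550, 300]], 13.0)
        np.testing.assert_allclose(vals, 7.0)

    def test_matches_independent_arc_length_walk(self, template_grid, rng):
        g = template_grid.like(rng.normal(size=(20, 20)))
        line = rng.uniform(30, 570, (6, 2))
        spacing = 17.0
        vals = sample_along_polyline(g, line, spacing)
        # oracle: walk the polyline segment by segment accumulating stations
        seg = np.diff(line, axis=0)
        lens = np.hypot(seg[:, 0], seg[:, 1])
        total = lens.sum()
        stations = list(np.linspace(0, total, int(np.ceil(total / spacing - 1e-9)) + 1))
        oracle = []
        for s in stations:
            acc = 0.0
            for a, d, L in zip(line[:-1], seg, lens):
                if s <= acc + L + 1e-9:
                    t = np.clip((s - acc) / L, 0, 1)
                    p = a + t * d
                    oracle.append(g.sample_nearest(p[0], p[1]))
                    break
                acc += L
        np.testing.assert_allclose(vals, np.array(oracle, dtype=float))

    def test_zero_length_polyline_single_sample(self, template_grid):
        st_pts = polyline_stations(np.array([[15.0, 585.0]]), 10.0)
        assert st_pts.shape == (1, 2)
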