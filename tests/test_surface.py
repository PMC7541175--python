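import itertools

import numpy as np
import pytest

from pathsel.grid import Grid
from pathsel.model import FittedModel
from pathsel.surface import (
    PredictionConfig,
    classify_breaks,
    corridor_patches,
    fisher_breaks,
    predict_surface,
    quantile_classes,
)


def make_fitted(terms, beta):
    beta = np.asarray(beta, dtype=float)
    return FittedModel(
        terms=list(terms), beta=beta, se=np.zeros_like(beta),
        vcov=np.zeros((len(beta), len(beta))), loglik=0.0, converged=True,
        n_strata_used=1, n_strata_total=1,
    )


class TestPredictSurface:
    def test_all_zero_coefficients_constant_surface(self, template_grid, rng):
        grids = {"slope": template_grid.like(rng.uniform(0, 30, (20, 20)))}
        fm = make_fitted(["slope"], [0.0])
        with pytest.warns(UserWarning, match="constant"):
            surf = predict_surface(fm, grids, {"slope": (10.0, 5.0)}, PredictionConfig(hold_covariates=()))
        assert np.nanstd(surf.linear_predictor.values) == 0

    def test_negative_slope_coefficient_monotone(self, template_grid):
        xs, _ = template_grid.cell_centers()
        grids = {"slope": template_grid.like(xs / 20.0)}
        fm = make_fitted(["slope"], [-0.7])
        surf = predict_surface(fm, grids, {"slope": (15.0, 8.0)}, PredictionConfig(hold_covariates=()))
        eta = surf.linear_predictor.values
        assert np.all(np.diff(eta, axis=1) < 0)

    def test_matches_cellwise_dot_product_oracle(self, template_grid, rng):
        names = ["slope", "wash", "veg"]
        grids = {n: template_grid.like(rng.uniform(0, 50, (20, 20))) for n in names}
        transform = {n: (25.0, 10.0 + i) for i, n in enumerate(names)}
        terms = ["slope", "slope^2", "wash", "veg", "slope:wash"]
        beta = rng.standard_normal(len(terms))
        fm = make_fitted(terms, beta)
        surf = predict_surface(fm, grids, transform, PredictionConfig(hold_covariates=()))
        # oracle: loop every cell, build the term vector by hand
        for r, c in itertools.product([0, 7, 19], [0, 3, 19]):
            z = {n: (grids[n].values[r, c] - transform[n][0]) / transform[n][1] for n in names}
            x = np.array([z["slope"], z["slope"] ** 2, z["wash"], z["veg"], z["slope"] * z["wash"]])
            assert surf.linear_predictor.values[r, c] == pytest.approx(float(x @ beta), abs=1e-10)

    def test_barriers_held_at_plateau(self, template_grid, rng):
        grids = {
            "slope": template_grid.like(rng.uniform(0, 30, (20, 20))),
            "fence": template_grid.like(rng.uniform(0, 4.2, (20, 20))),
        }
        tr = {"slope": (15.0, 8.0), "fence": (2.0, 1.0)}
        fm = make_fitted(["slope", "fence"], [-0.5, -0.8])
        surf = predict_surface(fm, grids, tr, PredictionConfig(hold_covariates=("fence",)))
        # fence contribution is the same constant everywhere: removing it
        # leaves a surface that differs by a constant
        fm2 = make_fitted(["slope"], [-0.5])
        surf2 = predict_surface(fm2, grids, {"slope": tr["slope"]}, PredictionConfig(hold_covariates=()))
        diff = surf.linear_predictor.values - surf2.linear_predictor.values
        assert np.nanstd(diff) == pytest.approx(0.0, abs=1e-12)
        held_z = (np.log(61.0) - 2.0) / 1.0
        assert diff[0, 0] == pytest.approx(-0.8 * held_z)

    def test_missing_grid_for_term_errors(self, template_grid):
        fm = make_fitted(["slope"], [1.0])
        with pytest.raises(ValueError, match="slope"):
            predict_surface(fm, {}, {}, PredictionConfig(hold_covariates=()))

    def test_classes_invariant_to_affine_predictor_change(self, template_grid, rng):
        grids = {"slope": template_grid.like(rng.uniform(0, 30, (20, 20)))}
        tr = {"slope": (15.0, 8.0)}
        cfg = PredictionConfig(hold_covariates=())
        s1 = predict_surface(make_fitted(["slope"], [-0.5]), grids, tr, cfg)
        s2 = predict_surface(make_fitted(["slope"], [-1.5]), grids, tr, cfg)  # eta scaled by 3
        np.testing.assert_array_equal(s1.mqi.values, s2.mqi.values)
        np.testing.assert_array_equal(s1.fisher_classes.values, s2.fisher_classes.values)


def brute_force_fisher(values, k):
    """Exhaustive enumeration of all ordered partitions (n <= 12, k <= 4)."""
    v = np.sort(values)
    n = len(v)
    best, best_sse = None, np.inf
    for cuts in itertools.combinations(range(1, n), k - 1):
        edges = [0, *cuts, n]
        sse = sum(np.sum((v[a:b] - v[a:b].mean()) ** 2) for a, b in zip(edges, edges[1:]))
        if sse < best_sse - 1e-12:
            best_sse, best = sse, cuts
    return best_sse


class TestFisherBreaks:
    def test_obvious_gap(self):
        cuts = fisher_breaks(np.array([1, 2, 3, 100, 101, 102], dtype=float), 2)
        assert cuts[0] == 3.0

    def test_matches_exhaustive_enumeration(self, rng):
        for _ in range(20):
            n = rng.integers(5, 13)
            k = rng.integers(2, min(5, n))
            v = rng.uniform(0, 100, n)
            cuts = fisher_breaks(v, k)
            cls = classify_breaks(np.sort(v), cuts)
            sse = sum(
                np.sum((np.sort(v)[cls == c] - np.sort(v)[cls == c].mean()) ** 2)
                for c in np.unique(cls)
            )
            assert sse == pytest.approx(brute_force_fisher(v, k), abs=1e-9)

    def test_k_equals_n_zero_variance(self, rng):
        v = rng.uniform(0, 10, 8)
        cuts = fisher_breaks(v, 8)
        cls = classify_breaks(np.sort(v), cuts)
        assert len(np.unique(cls)) == 8

    def test_beats_equal_interval_and_quantile_partitions(self, rng):
        for _ in range(10):
            v = rng.gamma(2, 10, 200)
            k = 5
            cuts = fisher_breaks(v, k)
            def total_sse(cutvals):
                cls = classify_breaks(v, np.asarray(cutvals))
                return sum(np.sum((v[cls == c] - v[cls == c].mean()) ** 2) for c in np.unique(cls))
            eq = np.linspace(v.min(), v.max(), k + 1)[1:-1]
            qu = np.quantile(v, np.linspace(0, 1, k + 1)[1:-1])
            assert total_sse(cuts) <= total_sse(eq) + 1e-9
            assert total_sse(cuts) <= total_sse(qu) + 1e-9


class TestQuantileClasses:
    def test_hundred_distinct_ten_per_class(self, rng):
        g = Grid(rng.permutation(100).reshape(10, 10).astype(float), 0, 300, 30)
        out = quantile_classes(g, 10)
        vals, counts = np.unique(out.values, return_counts=True)
        assert list(vals) == list(range(1, 11))
        assert all(c == 10 for c in counts)

    def test_constant_grid_single_class(self):
        g = Grid(np.full((5, 5), 3.0), 0, 150, 30)
        with pytest.warns(UserWarning, match="constant"):
            out = quantile_classes(g, 10)
        assert set(np.unique(out.values)) == {1.0}

    def test_ties_match_sort_based_oracle(self, rng):
        vals = rng.integers(0, 5, (8, 8)).astype(float)  # heavy ties
        g = Grid(vals, 0, 240, 30)
        out = quantile_classes(g, 4)
        flat = vals.ravel()
        order = np.sort(flat)
        for v, c in zip(flat, out.values.ravel()):
            rank = np.searchsorted(order, v, side="left")
            assert c == min(4, rank * 4 // len(flat) + 1)
        # all ties share one class
        for v in np.unique(flat):
            assert len(np.unique(out.values[vals == v])) == 1


class TestCorridorPatches:
    def test_rectangle_geometry(self):
        # 700 m x 2000 m rectangle of top-class cells on a 30-m grid
        vals = np.full((100, 100), 1.0)
        h, w = round(2000 / 30), round(700 / 30)  # 67 x 23 cells
        vals[10 : 10 + h, 40 : 40 + w] = 10.0
        g = Grid(vals, 0, 3000, 30)
        tab = corridor_patches(g, min_class=10)
        assert len(tab) == 1
        row = tab.iloc[0]
        assert row["area_ha"] == pytest.approx(h * w * 900 / 1e4)  # ~139 ha
        assert 1990 <= row["bbox_length_m"] <= 2020
        assert 660 <= row["min_width_m"] <= 750  # cell-quantized ~700
    def test_diagonal_blobs_connectivity(self):
        vals = np.zeros((10, 10))
        vals[2, 2] = vals[3, 3] = 5
        g = Grid(vals, 0, 300, 30)
        assert len(corridor_patches(g, 5, connectivity=8)) == 1
        assert len(corridor_patches(g, 5, connectivity=4)) == 2

    def test_empty_top_class(self):
        g = Grid(np.ones((5, 5)), 0, 150, 30)
        assert len(corridor_patches(g, 9)) == 0

    def test_patch_areas_sum_exactly(self, rng):
        vals = rng.integers(1, 11, (30, 30)).astype(float)
        g = Grid(vals, 0, 900, 30)
        tab = corridor_patches(g, 8)
        assert tab["n_cells"].sum() == int((vals >= 8).sum())
        assert tab["area_ha"].sum() == pytest.approx((vals >= 8).sum() * 900 / 1e4)
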