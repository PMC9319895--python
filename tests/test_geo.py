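"""Rasters, niche models, flood-fill ranges, overlap and permutation tests."""

import numpy as np
import pytest

import taxodelim as td
from taxodelim.geo import (
    OccurrenceSet,
    Raster,
    add_lonlat_layers,
    depth_average,
    raster_pca,
    read_ascii_grid,
    read_geotiff,
    read_occurrences,
    write_ascii_grid,
    write_geotiff,
    write_occurrences,
)


def grid_raster(values, **kw):
    return Raster(np.asarray(values, dtype=float), **kw)


def dfs_oracle(suit, seeds, threshold, connectivity):
    """Recursive flood fill, the slow way."""
    nr, nc = suit.shape
    visited = np.zeros_like(suit, dtype=bool)
    if connectivity == 8:
        nbrs = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]
    else:
        nbrs = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    stack = list(seeds)
    seen = set(seeds)
    while stack:
        r, c = stack.pop()
        for dr, dc in nbrs:
            rr, cc = r + dr, c + dc
            if 0 <= rr < nr and 0 <= cc < nc and (rr, cc) not in seen:
                if suit[rr, cc] >= threshold:
                    seen.add((rr, cc))
                    visited[rr, cc] = True
                    stack.append((rr, cc))
    for r, c in seeds:
        visited[r, c] = True
    out = np.where(visited, suit, 0.0)
    for r, c in seeds:
        out[r, c] = 1.0
    return out


class TestRasterPrep:
    def test_pca_perfectly_correlated_layers(self):
        rng = np.random.default_rng(0)
        base = rng.normal(size=(12, 15))
        stack = [grid_raster(base), grid_raster(2.0 * base + 5.0)]
        comps, frac = raster_pca(stack, n_keep=2)
        assert frac[0] == pytest.approx(1.0, abs=1e-9)

    def test_pca_equal_independent_layers(self):
        rng = np.random.default_rng(1)
        stack = [grid_raster(rng.normal(size=(60, 60))) for _ in range(3)]
        _, frac = raster_pca(stack, n_keep=3)
        assert np.allclose(frac, 1 / 3, atol=0.05)

    def test_pca_mask_propagation(self):
        rng = np.random.default_rng(2)
        vals = rng.normal(size=(10, 10))
        vals[3, 4] = np.nan
        stack = [grid_raster(vals), grid_raster(rng.normal(size=(10, 10)))]
        comps, _ = raster_pca(stack, n_keep=1)
        assert comps[0].mask[3, 4]
        assert comps[0].mask.sum() == 1

    def test_depth_average_rules(self):
        a = grid_raster([[1.0, 1.0]])
        b = grid_raster([[2.0, np.nan]])
        c = grid_raster([[3.0, 3.0]])
        (out,) = depth_average([[a, b, c]])
        assert out.values[0, 0] == 2.0
        assert out.values[0, 1] == 2.0  # mean of the two non-missing
        (same,) = depth_average([[a, a, a]])
        assert np.array_equal(same.values, a.values)

    def test_mismatched_grids_rejected(self):
        a = grid_raster(np.zeros((3, 3)))
        b = grid_raster(np.zeros((4, 3)))
        with pytest.raises(ValueError):
            raster_pca([a, b])

    def test_lonlat_layers(self):
        base = grid_raster(np.zeros((4, 5)), x_origin=10.0, y_origin=50.0,
                           cell_size=0.5)
        lon, lat = add_lonlat_layers([base])[-2:]
        assert lon.values[0, 0] == pytest.approx(10.25)
        assert lat.values[0, 0] == pytest.approx(49.75)
        assert lat.values[3, 0] == pytest.approx(48.25)


class TestFitEnm:
    def test_uniform_occurrence_environment(self):
        env = grid_raster([[0.0, 0.0, 5.0], [0.0, 5.0, 5.0]])
        occ = OccurrenceSet("t", [(0.5, -0.5), (1.5, -0.5), (0.5, -1.5)])
        suit = td.fit_enm(occ, [env], min_occurrences=3)
        assert suit.values[0, 0] == pytest.approx(1.0)
        assert suit.values[0, 2] < 1e-6

    def test_recovers_true_niche(self, small_landscape):
        land = small_landscape
        suit = td.fit_enm(land.occurrences["A"], land.layers)
        from scipy.stats import spearmanr

        rho = spearmanr(
            suit.values.ravel(), land.true_suitability["A"].values.ravel()
        ).statistic
        assert rho > 0.8

    def test_external_raster_validated(self):
        env = grid_raster(np.zeros((3, 3)))
        bad = grid_raster(np.full((3, 3), 1.2))
        with pytest.raises(ValueError, match=r"\[0, 1\]"):
            td.fit_enm(
                OccurrenceSet("t", [(0.5, -0.5)]), [env],
                model="external-raster", external=bad,
            )

    def test_too_few_occurrences(self):
        env = grid_raster(np.zeros((5, 5)))
        with pytest.raises(ValueError, match=">= 5"):
            td.fit_enm(OccurrenceSet("t", [(0.5, -0.5)]), [env])


class TestApproximateDistribution:
    def test_blocked_middle_row(self):
        """Occurrence in the top block: the bottom block stays 0 despite
        high suitability, because a zero row disconnects it."""
        suit = np.full((5, 5), 0.9)
        suit[2, :] = 0.0
        r = grid_raster(suit)
        occ = OccurrenceSet("t", [r.center_of(0, 2)])
        dist = td.approximate_distribution(r, occ, threshold=0.25)
        assert (dist.raster.values[3:, :] == 0.0).all()
        assert (dist.raster.values[:2, :] >= 0.25).all()
        assert dist.raster.values[0, 2] == 1.0

    def test_everything_reachable(self):
        r = grid_raster(np.full((4, 4), 0.5))
        occ = OccurrenceSet("t", [r.center_of(1, 1)])
        dist = td.approximate_distribution(r, occ, threshold=0.25)
        assert (dist.raster.values > 0).all()

    def test_subthreshold_seed_still_marked(self):
        suit = np.zeros((3, 3))
        suit[1, 1] = 0.1
        r = grid_raster(suit)
        occ = OccurrenceSet("t", [r.center_of(1, 1)])
        dist = td.approximate_distribution(r, occ, threshold=0.25)
        assert dist.raster.values[1, 1] == 1.0

    @pytest.mark.parametrize("connectivity", [4, 8])
    def test_matches_dfs_oracle(self, connectivity):
        rng = np.random.default_rng(3)
        for _ in range(5):
            suit = rng.random((20, 20))
            r = grid_raster(suit)
            seeds = [
                (int(rng.integers(20)), int(rng.integers(20)))
                for _ in range(3)
            ]
            occ = OccurrenceSet("t", [r.center_of(*s) for s in seeds])
            dist = td.approximate_distribution(
                r, occ, threshold=0.4, connectivity=connectivity
            )
            expect = dfs_oracle(suit, seeds, 0.4, connectivity)
            assert np.allclose(dist.raster.values, expect, atol=1e-12)


class TestOverlapStats:
    def test_identical_full_rasters(self):
        r = grid_raster(np.ones((3, 3)))
        d = td.DistributionRaster(r, 0.25, 8)
        assert td.pairwise_overlap(d, d) == 1.0

    def test_disjoint_supports(self):
        a = np.zeros((2, 4))
        a[:, :2] = 1.0
        b = np.zeros((2, 4))
        b[:, 2:] = 1.0
        da = td.DistributionRaster(grid_raster(a), 0.25, 8)
        db = td.DistributionRaster(grid_raster(b), 0.25, 8)
        assert td.pairwise_overlap(da, db) == 0.0

    def test_hand_case_two_thirds(self):
        a = np.zeros((3, 3))
        a[0, :2] = a[1, :2] = 0.6
        b = np.zeros((3, 3))
        b[0, 0] = b[0, 1] = 0.5
        b[2, 2] = 0.9
        da = td.DistributionRaster(grid_raster(a), 0.25, 8)
        db = td.DistributionRaster(grid_raster(b), 0.25, 8)
        # product on the two shared cells = 0.3 >= 0.25; denominator min(4, 3)
        assert td.pairwise_overlap(da, db) == pytest.approx(2 / 3)
        assert td.pairwise_overlap(db, da) == pytest.approx(2 / 3)

    def test_monotone_in_cell_values(self):
        rng = np.random.default_rng(4)
        a = rng.random((5, 5))
        b = rng.random((5, 5))
        da = td.DistributionRaster(grid_raster(a), 0.25, 8)
        db = td.DistributionRaster(grid_raster(b), 0.25, 8)
        base = td.pairwise_overlap(da, db)
        b2 = b.copy()
        b2[2, 2] = 1.0
        db2 = td.DistributionRaster(grid_raster(b2), 0.25, 8)
        assert td.pairwise_overlap(da, db2) >= base - 1e-12

    def test_empty_distribution_flagged(self):
        da = td.DistributionRaster(grid_raster(np.zeros((2, 2))), 0.25, 8)
        db = td.DistributionRaster(grid_raster(np.ones((2, 2))), 0.25, 8)
        with pytest.raises(ValueError, match="empty"):
            td.pairwise_overlap(da, db)

    def test_schoener_identity_and_disjoint(self):
        rng = np.random.default_rng(5)
        x = grid_raster(rng.random((4, 4)))
        assert td.schoener_d(x, x) == pytest.approx(1.0)
        a = np.zeros((1, 4))
        a[0, :2] = 1.0
        b = np.zeros((1, 4))
        b[0, 2:] = 1.0
        assert td.schoener_d(grid_raster(a), grid_raster(b)) == 0.0

    def test_schoener_hand_case(self):
        pa = grid_raster(np.array([[0.5, 0.5, 0.0]]))
        pb = grid_raster(np.array([[0.0, 0.5, 0.5]]))
        assert td.schoener_d(pa, pb) == pytest.approx(0.5)

    def test_schoener_triangle_type_bound(self):
        rng = np.random.default_rng(6)
        for _ in range(10):
            a, b, c = (grid_raster(rng.random((4, 4))) for _ in range(3))
            dab = td.schoener_d(a, b)
            assert abs(td.schoener_d(a, c) - td.schoener_d(b, c)) <= (
                1.0 - dab + 1e-12
            )


class TestPermutationTests:
    def test_sympatry_symmetric_and_extremes(self, small_landscape):
        land = small_landscape
        occ_a, occ_b = land.occurrences["A"], land.occurrences["B"]
        r1 = td.sympatry_test(occ_a, occ_b, land.layers, n_perm=49, seed=7)
        r2 = td.sympatry_test(occ_b, occ_a, land.layers, n_perm=49, seed=7)
        assert r1.overlap == r2.overlap and r1.p == r2.p

    def test_identical_occurrences_maximal_sympatry(self, small_landscape):
        """Identical occurrence sets are maximally sympatric: the observed
        overlap equals the self-overlap of the common distribution raster
        (below 1 because the product step squares non-binary suitability
        values before re-thresholding) and sympatry is not rejected."""
        land = small_landscape
        occ = land.occurrences["A"]
        twin = OccurrenceSet("twin", occ.points.copy())
        res = td.sympatry_test(occ, twin, land.layers, n_perm=49, seed=8)
        layers = add_lonlat_layers(land.layers)
        dist = td.approximate_distribution(
            td.fit_enm(occ, layers), occ, 0.25
        )
        assert res.overlap == pytest.approx(td.pairwise_overlap(dist, dist))
        assert res.p >= 0.5  # far from the allopatric (lower) tail

    def test_allopatric_minimum_p(self):
        land = td.simulate_landscape(
            td.LandscapeModel(
                scenario="allopatric", seed=9, niche_width_scale=0.7,
                n_occurrences=40,
            )
        )
        res = td.sympatry_test(
            land.occurrences["A"], land.occurrences["B"], land.layers,
            n_perm=99, seed=10,
        )
        assert res.p == pytest.approx(1.0 / 100.0)

    def test_equivalency_symmetric_and_extremes(self, small_landscape):
        land = small_landscape
        occ_a, occ_b = land.occurrences["A"], land.occurrences["B"]
        r1 = td.niche_equivalency_test(occ_a, occ_b, land.layers, n_perm=49,
                                       seed=11)
        r2 = td.niche_equivalency_test(occ_b, occ_a, land.layers, n_perm=49,
                                       seed=11)
        assert r1.overlap == r2.overlap and r1.p == r2.p

    def test_equivalency_disjoint_niches(self):
        land = td.simulate_landscape(
            td.LandscapeModel(
                scenario="allopatric", seed=12, niche_width_scale=0.7,
                n_occurrences=40,
            )
        )
        res = td.niche_equivalency_test(
            land.occurrences["A"], land.occurrences["B"], land.layers,
            n_perm=99, seed=13,
        )
        assert res.p == pytest.approx(1.0 / 100.0)


class TestIO:
    def test_ascii_grid_roundtrip(self, tmp_path):
        rng = np.random.default_rng(14)
        vals = rng.random((6, 7))
        vals[2, 3] = np.nan
        r = grid_raster(vals, x_origin=-3.0, y_origin=48.0, cell_size=0.25)
        path = tmp_path / "grid.asc"
        write_ascii_grid(r, path)
        back = read_ascii_grid(path)
        assert back.shape == r.shape
        assert back.mask[2, 3]
        valid = ~r.mask
        assert np.allclose(back.values[valid], r.values[valid], rtol=1e-6)
        assert back.x_origin == pytest.approx(-3.0)
        assert back.y_origin == pytest.approx(48.0)

    def test_geotiff_roundtrip(self, tmp_path):
        rng = np.random.default_rng(15)
        r = grid_raster(
            rng.random((5, 4)).astype(np.float32),
            x_origin=2.0, y_origin=44.0, cell_size=0.1,
        )
        path = tmp_path / "grid.tif"
        write_geotiff(r, path)
        back = read_geotiff(path)
        assert np.allclose(back.values, r.values, atol=1e-6)
        assert back.cell_size == pytest.approx(0.1)
        assert back.x_origin == pytest.approx(2.0)

    def test_occurrence_csv_roundtrip(self, tmp_path):
        occs = [
            OccurrenceSet("a", [(1.0, 2.0), (3.0, 4.0)]),
            OccurrenceSet("b", [(5.0, 6.0)]),
        ]
        path = tmp_path / "occ.csv"
        write_occurrences(occs, path)
        back = read_occurrences(path)
        assert [o.taxon for o in back] == ["a", "b"]
        assert np.allclose(back[0].points, occs[0].points)

    def test_great_circle_distance(self):
        # one degree of latitude is ~111.2 km
        assert td.geo.great_circle_km(0, 0, 0, 1) == pytest.approx(111.2, abs=0.5)


class TestSimulateLandscape:
    def test_determinism(self):
        m = td.LandscapeModel(seed=16)
        l1 = td.simulate_landscape(m)
        l2 = td.simulate_landscape(m)
        for a, b in zip(l1.layers, l2.layers):
            assert np.array_equal(a.values, b.values)
        for t in m.taxa:
            assert np.array_equal(
                l1.occurrences[t].points, l2.occurrences[t].points
            )

    def test_sympatric_identical_true_suitability(self):
        land = td.simulate_landscape(
            td.LandscapeModel(scenario="sympatric", seed=17)
        )
        assert (
            td.schoener_d(
                land.true_suitability["A"], land.true_suitability["B"]
            )
            == pytest.approx(1.0)
        )

    def test_allopatric_true_ranges_disjoint(self):
        land = td.simulate_landscape(
            td.LandscapeModel(
                scenario="allopatric", seed=18, niche_width_scale=0.7
            )
        )
        prod = (
            land.true_suitability["A"].values
            * land.true_suitability["B"].values
        )
        assert (prod >= 0.25).sum() == 0

    def test_occurrences_on_positive_cells(self, small_landscape):
        land = small_landscape
        for t, occ in land.occurrences.items():
            suit = land.true_suitability[t]
            vals = [suit.values[r, c] for r, c in occ.cells]
            assert min(vals) > 0.0

    def test_layers_finite(self, small_landscape):
        for layer in small_landscape.layers:
            assert np.isfinite(layer.values).all()

    def test_oversampling_rejected(self):
        with pytest.raises(ValueError):
            td.simulate_landscape(
                td.LandscapeModel(
                    n_rows=5, n_cols=5, n_occurrences=50, seed=19
                )
            )
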