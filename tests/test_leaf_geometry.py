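"""Leaf simulation, constrained meshing, ARAP straightening, texture."""

import numpy as np
import pytest
from shapely.geometry import Polygon

import taxodelim as td
from taxodelim.leaf import LeafAnnotation, build_mesh, map_texture, straighten
from taxodelim.leaf.stats import ldi


class TestSimulateLeaf:
    def test_zero_curvature_is_identity(self):
        bent, straight = td.simulate_leaf(
            td.LeafModel(bend_curvature=0.0, seed=1)
        )
        assert np.array_equal(bent.contour, straight.contour)
        assert np.array_equal(bent.midvein, straight.midvein)

    @pytest.mark.parametrize("kappa", [0.001, -0.0015, 0.002])
    def test_area_preserved_by_arc_map(self, kappa):
        bent, straight = td.simulate_leaf(
            td.LeafModel(bend_curvature=kappa, seed=2)
        )
        ratio = Polygon(bent.contour).area / Polygon(straight.contour).area
        assert abs(ratio - 1.0) < 0.01

    def test_vertex_counts_and_arc_length(self):
        bent, straight = td.simulate_leaf(
            td.LeafModel(bend_curvature=0.002, seed=3)
        )
        assert len(bent.contour) == len(straight.contour)
        assert len(bent.midvein) == len(straight.midvein)
        assert bent.midvein_arc_length() == pytest.approx(
            straight.midvein_arc_length(), abs=1e-9
        )

    def test_smooth_outline_ldi_matches_dense_sampling(self):
        """dissection = 0: the polygon LDI matches the densely sampled
        smooth outline within 5%."""
        coarse, _ = td.simulate_leaf(
            td.LeafModel(dissection=0.0, contour_points=128, seed=4)
        )
        dense, _ = td.simulate_leaf(
            td.LeafModel(dissection=0.0, contour_points=4096, seed=4)
        )
        assert ldi(coarse.contour) == pytest.approx(
            ldi(dense.contour), rel=0.05
        )

    def test_excessive_curvature_rejected(self):
        with pytest.raises(ValueError, match="curvature"):
            td.simulate_leaf(td.LeafModel(bend_curvature=0.02, seed=5))

    def test_determinism(self):
        m = td.LeafModel(bend_curvature=0.001, noise=0.05, seed=6)
        b1, s1 = td.simulate_leaf(m)
        b2, s2 = td.simulate_leaf(m)
        assert np.array_equal(b1.contour, b2.contour)
        assert np.array_equal(s1.contour, s2.contour)

    def test_contour_simple_and_midvein_inside(self):
        for seed in range(5):
            bent, straight = td.simulate_leaf(
                td.LeafModel(dissection=2.0, bend_curvature=0.0015,
                             noise=0.05, seed=seed)
            )
            bent.validate()
            straight.validate()


class TestBuildMesh:
    def test_quadrilateral_with_interior_midvein(self):
        leaf = LeafAnnotation(
            np.array([[0.0, 0], [10, 0], [10, 6], [0, 6]]),
            np.array([[1.0, 3.0], [9.0, 3.0]]),
        )
        mesh = build_mesh(leaf)
        assert Polygon(mesh.boundary_polygon()).area == pytest.approx(60.0)
        assert len(mesh.midvein_vertex_ids) >= 2

    def test_partition_property(self, bent_leaf_pair):
        bent, _ = bent_leaf_pair
        mesh = build_mesh(bent)
        assert mesh.triangle_areas().sum() == pytest.approx(
            Polygon(bent.contour).area, rel=1e-9
        )

    def test_refinement_increases_triangle_count(self, bent_leaf_pair):
        bent, _ = bent_leaf_pair
        coarse = build_mesh(bent, max_triangle_area=800.0)
        fine = build_mesh(bent, max_triangle_area=200.0)
        assert len(fine.triangles) >= 2 * len(coarse.triangles)
        assert fine.triangle_areas().max() <= 200.0

    def test_constrained_edges_present(self, bent_leaf_pair):
        bent, _ = bent_leaf_pair
        mesh = build_mesh(bent, max_triangle_area=400.0)
        edges = mesh.edge_set()
        for a, b in mesh.constrained_edges:
            assert (min(a, b), max(a, b)) in edges
        assert (mesh.triangle_areas() > 0).all()

    def test_degenerate_polygon_rejected(self):
        leaf = LeafAnnotation(
            np.array([[0.0, 0], [1, 0], [2, 0], [3, 0]]),
            np.array([[0.5, 0.0], [2.5, 0.0]]),
        )
        with pytest.raises(ValueError):
            build_mesh(leaf)


class TestStraighten:
    def test_already_straight_is_fixed_point(self):
        _, straight = td.simulate_leaf(td.LeafModel(seed=8))
        mesh = build_mesh(straight, max_triangle_area=500.0)
        # canonical frame: midvein already on +x from its base
        base = mesh.vertices[mesh.midvein_vertex_ids[0]]
        canon = mesh.with_vertices(mesh.vertices - base)
        res = straighten(canon)
        assert np.abs(res.mesh.vertices - canon.vertices).max() < 1e-6

    def test_bent_leaf_recovery(self, bent_leaf_pair):
        """kappa * length = 0.8: contour within 2% of ground truth, area
        within 5%, midvein exactly collinear."""
        bent, straight = bent_leaf_pair
        mesh = build_mesh(bent, max_triangle_area=200.0)
        res = straighten(mesh)
        assert res.converged
        mid = res.mesh.midvein()
        assert np.abs(mid[:, 1]).max() < 1e-9 * 400.0
        # mesh midvein chain length conserved exactly by construction
        out_len = np.linalg.norm(np.diff(mid, axis=0), axis=1).sum()
        in_len = np.linalg.norm(np.diff(mesh.midvein(), axis=0), axis=1).sum()
        assert out_len == pytest.approx(in_len, abs=1e-9)
        # anchored at the basal contour point = origin of the truth frame
        truth = straight.contour
        dev = np.linalg.norm(
            res.mesh.vertices[mesh.input_contour_ids] - truth, axis=1
        )
        assert dev.mean() < 0.02 * 400.0
        area_ratio = Polygon(res.contour).area / Polygon(straight.contour).area
        assert abs(area_ratio - 1.0) < 0.05

    def test_idempotence(self, bent_leaf_pair):
        bent, _ = bent_leaf_pair
        mesh = build_mesh(bent, max_triangle_area=300.0)
        once = straighten(mesh)
        twice = straighten(once.mesh)
        assert np.abs(twice.mesh.vertices - once.mesh.vertices).max() < 1e-6

    def test_contour_perimeter_conserved(self, bent_leaf_pair):
        bent, _ = bent_leaf_pair
        mesh = build_mesh(bent, max_triangle_area=300.0)
        res = straighten(mesh)
        p_in = Polygon(mesh.boundary_polygon()).length
        p_out = Polygon(res.contour).length
        assert abs(p_out / p_in - 1.0) < 0.05


class TestMapTexture:
    def test_identity_deformation(self, bent_leaf_pair):
        bent, _ = bent_leaf_pair
        mesh = build_mesh(bent, max_triangle_area=500.0)
        rng = np.random.default_rng(0)
        lo = mesh.vertices.min(axis=0)
        shifted = mesh.with_vertices(mesh.vertices - lo + 0.0)
        h = int(np.ceil(shifted.vertices[:, 1].max())) + 2
        w = int(np.ceil(shifted.vertices[:, 0].max())) + 2
        img = rng.random((h, w))
        out = map_texture(shifted, shifted, img, background=-1.0)
        inside = out >= 0
        assert inside.sum() > 0.5 * inside.size * 0.2
        # sampled values match the source at the same locations
        ys, xs = np.where(inside)
        src = img[
            np.clip(np.round(ys + 0.0).astype(int), 0, h - 1),
            np.clip(np.round(xs + 0.0).astype(int), 0, w - 1),
        ]
        assert np.median(np.abs(out[inside] - src)) < 0.2

    def test_constant_source_constant_output(self, bent_leaf_pair):
        bent, _ = bent_leaf_pair
        mesh = build_mesh(bent, max_triangle_area=500.0)
        res = straighten(mesh)
        img = np.full((700, 700), 3.5)
        out = map_texture(mesh, res.mesh, img, background=0.0)
        vals = out[out != 0.0]
        assert np.allclose(vals, 3.5)

    def test_foreground_area_conserved(self, bent_leaf_pair):
        """Bent-to-straight mapping keeps the leaf pixel count within 5%."""
        bent, _ = bent_leaf_pair
        mesh = build_mesh(bent, max_triangle_area=300.0)
        res = straighten(mesh)
        shift = -mesh.vertices.min(axis=0)
        src_mesh = mesh.with_vertices(mesh.vertices + shift)
        h = int(np.ceil(src_mesh.vertices[:, 1].max())) + 2
        w = int(np.ceil(src_mesh.vertices[:, 0].max())) + 2
        img = np.ones((h, w))
        out = map_texture(src_mesh, res.mesh, img, background=0.0)
        n_out = (out > 0.5).sum()
        n_in = Polygon(bent.contour).area  # 1-valued pixels ~ polygon area
        assert abs(n_out / n_in - 1.0) < 0.05

    def test_rasterized_mask_area_matches_polygon(self, bent_leaf_pair):
        from taxodelim.leaf.texture import rasterize_mask

        bent, _ = bent_leaf_pair
        mask = rasterize_mask(bent.contour)
        assert abs(mask.sum() / Polygon(bent.contour).area - 1.0) < 0.01

    def test_topology_mismatch_rejected(self, bent_leaf_pair):
        bent, _ = bent_leaf_pair
        m1 = build_mesh(bent, max_triangle_area=500.0)
        m2 = build_mesh(bent, max_triangle_area=200.0)
        with pytest.raises(ValueError, match="topology"):
            map_texture(m1, m2, np.zeros((10, 10)))
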