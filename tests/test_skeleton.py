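import numpy as np
import pytest

from angiotomo import (
    VesselMask,
    filter_by_diameter,
    grow_tree,
    skeleton_to_graph,
    skeletonize,
)
from angiotomo.phantom import rasterize_mask

from conftest import SPACING, make_cylinder_mask, recovery_tree_spec


def graph_of(mask: np.ndarray, prune: float = 2.0):
    return skeleton_to_graph(skeletonize(VesselMask(mask, SPACING)), prune)


class TestSkeletonize:
    def test_empty_mask_gives_empty_skeleton(self):
        sk = skeletonize(VesselMask(np.zeros((8, 8, 8), bool), SPACING))
        assert sk.n_voxels == 0
        assert skeleton_to_graph(sk).n_branches == 0

    def test_isolated_voxel_is_its_own_skeleton(self):
        m = np.zeros((8, 8, 8), bool)
        m[4, 4, 4] = True
        sk = skeletonize(VesselMask(m, SPACING))
        np.testing.assert_array_equal(sk.voxels, [[4, 4, 4]])

    def test_cylinder_centerline_voxel_count(self):
        """A solid axis-aligned cylinder of axial extent L reduces to a
        single path of about L voxels."""
        L = 41
        mask = make_cylinder_mask(4.0, length_vox=L)
        sk = skeletonize(VesselMask(mask, SPACING))
        g = skeleton_to_graph(sk)
        assert g.n_branches == 1
        assert g.n_nodes == 2
        assert abs(sk.n_voxels - L) <= 2

    def test_skeleton_inside_mask(self):
        truth = grow_tree(recovery_tree_spec(seed=4))
        mask = rasterize_mask(truth)
        sk = skeletonize(VesselMask(mask, SPACING))
        assert mask[sk.voxels[:, 0], sk.voxels[:, 1], sk.voxels[:, 2]].all()
        assert (sk.radius_um > 0).all()

    def test_torus_preserves_cycle(self):
        m = np.zeros((40, 60, 60), bool)
        zz, yy, xx = np.ogrid[:40, :60, :60]
        ring = np.sqrt((yy - 30.0) ** 2 + (xx - 30.0) ** 2)
        m[((ring - 15) ** 2 + (zz - 20.0) ** 2) <= 9] = True
        g = graph_of(m)
        cycles = g.n_branches - g.n_nodes + g.n_components()
        assert cycles == 1


class TestVectorization:
    def test_straight_path(self):
        m = np.zeros((30, 9, 9), bool)
        m[3:27, 4, 4] = True
        g = graph_of(m, prune=0.0)
        assert g.n_branches == 1
        kinds = sorted(n.kind for n in g.nodes)
        assert kinds == ["endpoint", "endpoint"]

    def test_y_shape_fixture(self):
        """Three arms meeting at one voxel → 3 branches, 1 junction + 3
        endpoints."""
        m = np.zeros((24, 24, 24), bool)
        m[12, 12, 4:13] = True  # arm along x ending at center
        m[12, 4:13, 12] = True  # arm along y
        m[13:21, 12, 12] = True  # arm along z
        g = graph_of(m, prune=0.0)
        assert g.n_branches == 3
        assert g.n_nodes == 4
        assert sum(1 for n in g.nodes if n.kind == "junction") == 1
        junction = next(n for n in g.nodes if n.kind == "junction")
        assert junction.degree == 3

    def test_partition_property(self):
        """Interior path voxels plus node voxels account for every skeleton
        voxel exactly once."""
        truth = grow_tree(recovery_tree_spec(seed=6))
        sk = skeletonize(VesselMask(rasterize_mask(truth), SPACING))
        g = skeleton_to_graph(sk, prune_factor=0.0)
        interior = set()
        for b in g.branches:
            for v in b.path[1:-1]:
                interior.add(tuple(v))
        endpoints = {tuple(v) for b in g.branches for v in (b.path[0], b.path[-1])}
        assert len(interior) + len(endpoints - interior) == sk.n_voxels

    def test_no_degree2_nodes(self):
        for seed in (1, 2, 3):
            truth = grow_tree(recovery_tree_spec(seed=seed))
            g = graph_of(rasterize_mask(truth))
            cycle_ids = set(g.provenance.get("cycle_nodes", []))
            for n in g.nodes:
                if n.id in cycle_ids:
                    continue
                assert n.degree != 2 or n.kind == "endpoint" and n.degree == 0

    def test_branch_diameter_of_cylinder(self):
        mask = make_cylinder_mask(4.0, length_vox=41)
        g = graph_of(mask)
        assert g.branches[0].diameter_um == pytest.approx(41.6, abs=SPACING)

    def test_determinism(self):
        truth = grow_tree(recovery_tree_spec(seed=2))
        mask = rasterize_mask(truth)
        g1, g2 = graph_of(mask), graph_of(mask)
        assert [(b.node_a, b.node_b) for b in g1.branches] == [
            (b.node_a, b.node_b) for b in g2.branches
        ]
        for a, b in zip(g1.branches, g2.branches):
            np.testing.assert_array_equal(a.path, b.path)

    def test_connectivity_preserved(self):
        # two disjoint tubes → two graph components
        m = np.zeros((40, 40, 40), bool)
        m[5:35, 8, 8] = True
        m[5:35, 28, 28] = True
        from scipy import ndimage

        g = graph_of(ndimage.binary_dilation(m, np.ones((3, 3, 3))), prune=0.0)
        assert g.n_components() == 2

    def test_spur_pruning(self):
        # a long tube with a 2-voxel spur: the spur disappears at prune 2
        m = np.zeros((40, 15, 15), bool)
        m[4:36, 7, 7] = True
        m[20, 8, 8] = True
        m[20, 9, 9] = True
        g0 = graph_of(m, prune=0.0)
        g2 = graph_of(m, prune=2.0)
        assert g0.n_branches >= 3
        assert g2.n_branches == 1
        assert g2.provenance["pruned_branches"] >= 1


class TestFilterByDiameter:
    def _graph(self):
        truth = grow_tree(recovery_tree_spec(seed=2))
        return graph_of(rasterize_mask(truth))

    def test_identity_with_full_range(self):
        g = self._graph()
        out = filter_by_diameter(g)
        assert out.n_branches == g.n_branches
        assert out.n_nodes == g.n_nodes

    def test_diameter_window(self):
        import copy

        g = self._graph()
        for b, d in zip(g.branches, (8.0, 15.0, 35.0)):
            b.diameter_um = d
        out = filter_by_diameter(g, max_um=30.0)
        assert out.n_branches == sum(1 for b in g.branches if b.diameter_um < 30.0)

    def test_orphan_nodes_dropped_and_degrees_recomputed(self):
        g = self._graph()
        out = filter_by_diameter(g, min_um=1e9, max_um=2e9)
        assert out.n_branches == 0
        assert out.n_nodes == 0

    def test_invalid_range_fails(self):
        with pytest.raises(ValueError, match="exceeds"):
            filter_by_diameter(self._graph(), min_um=30.0, max_um=10.0)

    def test_filter_keeps_penumbral_microvessels(self):
        from angiotomo import TreeSpec, condition_template, grow_forest

        shape = (64, 64, 64)
        truth = grow_forest(TreeSpec(seed=3, volume_shape=shape), condition_template("6h", shape))
        g = graph_of(rasterize_mask(truth))
        kept = filter_by_diameter(g, max_um=30.0)
        # the added microvessels (true radii ≤ 10 μm → diameters ≤ 20) survive
        assert kept.n_branches >= sum(1 for d in g.diameters_um() if d < 25.0) * 0.8
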