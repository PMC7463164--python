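import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from optoreg.cortical_projection import (
    ChannelTable,
    attach_midpoints,
    channel_midpoints,
    pair_channels,
    pair_channels_from_file,
    project_to_surface,
)
from optoreg.errors import ValidationError
from optoreg.geometry_io import (
    MNI,
    PHOTO,
    FrameMismatchError,
    OptodeSet,
    PointTable,
    SurfaceMesh,
)
from optoreg.synthetic_data import icosphere


def oracle_closest(point, triangles):
    """Independent closest-point oracle: candidate enumeration.

    Candidates per triangle: the orthogonal projection onto the plane when
    its barycentric coordinates are all non-negative, plus the closest point
    on each of the three edge segments. The global minimum over all
    candidates is the exact closest point.
    """
    best, best_d = None, np.inf
    for tri in triangles:
        a, b, c = tri
        candidates = []
        n = np.cross(b - a, c - a)
        nn = n / np.linalg.norm(n)
        foot = point - np.dot(point - a, nn) * nn
        # barycentric test via the 2x2 normal system
        m = np.array([[np.dot(b - a, b - a), np.dot(b - a, c - a)],
                      [np.dot(b - a, c - a), np.dot(c - a, c - a)]])
        rhs = np.array([np.dot(foot - a, b - a), np.dot(foot - a, c - a)])
        u, v = np.linalg.solve(m, rhs)
        if u >= 0 and v >= 0 and u + v <= 1:
            candidates.append(foot)
        for p0, p1 in ((a, b), (b, c), (c, a)):
            seg = p1 - p0
            t = np.clip(np.dot(point - p0, seg) / np.dot(seg, seg), 0.0, 1.0)
            candidates.append(p0 + t * seg)
        for cand in candidates:
            d = np.linalg.norm(point - cand)
            if d < best_d:
                best, best_d = cand, d
    return best, best_d


def random_soup(rng, n_triangles):
    verts = rng.normal(scale=50.0, size=(3 * n_triangles, 3))
    faces = np.arange(3 * n_triangles).reshape(-1, 3)
    return SurfaceMesh(verts, faces, MNI)


class TestProjectToSurface:
    def test_vertex_maps_to_itself(self, square_mesh):
        points = PointTable(["p"], [[1.0, 1.0, 0.0]], MNI)
        result = project_to_surface(points, square_mesh)
        np.testing.assert_allclose(result.points.coords[0], [1, 1, 0])
        assert result.distances[0] == 0

    def test_foot_of_perpendicular(self):
        tri = SurfaceMesh([[-1, -1, 0], [2, -1, 0], [0, 2, 0]], [[0, 1, 2]], MNI)
        points = PointTable(["p"], [[0.0, 0.0, 10.0]], MNI)
        result = project_to_surface(points, tri)
        np.testing.assert_allclose(result.points.coords[0], [0, 0, 0],
                                   atol=1e-12)
        assert result.distances[0] == pytest.approx(10.0)

    def test_matches_bruteforce_oracle(self):
        rng = np.random.default_rng(42)
        mesh = random_soup(rng, 50)
        points = rng.normal(scale=80.0, size=(40, 3))
        result = project_to_surface(
            PointTable([str(i) for i in range(40)], points, MNI), mesh)
        tri = mesh.triangles()
        for i, p in enumerate(points):
            expected, expected_d = oracle_closest(p, tri)
            assert result.distances[i] == pytest.approx(expected_d, abs=1e-9)
            np.testing.assert_allclose(result.points.coords[i], expected,
                                       atol=1e-9)

    def test_idempotent(self, default_head):
        rng = np.random.default_rng(0)
        points = PointTable([str(i) for i in range(20)],
                            rng.normal(scale=120, size=(20, 3)), MNI)
        once = project_to_surface(points, default_head.scalp)
        twice = project_to_surface(once.points, default_head.scalp)
        assert np.abs(twice.points.coords - once.points.coords).max() < 1e-9

    def test_never_farther_than_any_vertex(self, square_mesh):
        rng = np.random.default_rng(1)
        points = rng.normal(scale=2.0, size=(50, 3))
        result = project_to_surface(
            PointTable([str(i) for i in range(50)], points, MNI), square_mesh)
        for i, p in enumerate(points):
            vertex_d = np.linalg.norm(square_mesh.vertices - p, axis=1).min()
            assert result.distances[i] <= vertex_d + 1e-12

    def test_frame_mismatch(self, square_mesh):
        points = PointTable(["p"], [[0, 0, 1]], PHOTO)
        with pytest.raises(FrameMismatchError):
            project_to_surface(points, square_mesh)

    def test_empty_mesh_rejected(self):
        with pytest.raises(ValidationError):
            mesh = SurfaceMesh(np.zeros((0, 3)), np.zeros((0, 3)), MNI)
            project_to_surface(PointTable(["p"], [[0, 0, 0]], MNI), mesh)

    def test_ray_method_on_sphere(self, unit_sphere_head):
        # outward points pull back to the surface along the centroid ray
        points = PointTable(["a", "b"], [[0, 0, 2.0], [1.5, 1.5, 0.0]], MNI)
        result = project_to_surface(points, unit_sphere_head.scalp, "ray")
        assert not result.errors
        radii = np.linalg.norm(result.points.coords, axis=1)
        assert np.all(np.abs(radii - 1.0) < 0.05)  # mesh chord tolerance

    def test_ray_method_miss_is_recorded(self):
        # two distant triangles whose area centroid floats in empty space:
        # a segment to the centroid at constant z=5 crosses neither plane
        mesh = SurfaceMesh(
            [[0, 0, 0], [1, 0, 0], [0, 1, 0],
             [100, 0, 10], [101, 0, 10], [100, 1, 10]],
            [[0, 1, 2], [3, 4, 5]], MNI)
        points = PointTable(["miss"], [[0.0, 50.0, 5.0]], MNI)
        result = project_to_surface(points, mesh, "ray")
        assert result.failed_ids == ["miss"]
        # the failed point keeps its input position, the run continues
        np.testing.assert_allclose(result.points.position("miss"),
                                   [0.0, 50.0, 5.0])

    def test_unknown_method(self, square_mesh):
        with pytest.raises(ValidationError):
            project_to_surface(PointTable(["p"], [[0, 0, 1]], MNI),
                               square_mesh, "nearest-voxel")


def cap_from_coords(coords_sources, coords_detectors):
    ids = [f"S{i + 1}" for i in range(len(coords_sources))]
    ids += [f"D{i + 1:02d}" for i in range(len(coords_detectors))]
    roles = ["source"] * len(coords_sources) + ["detector"] * len(coords_detectors)
    return OptodeSet.from_arrays(
        ids, roles, np.vstack([coords_sources, coords_detectors]), MNI)


class TestPairChannels:
    def test_single_pair_at_nominal(self):
        cap = cap_from_coords([[0, 0, 0]], [[28.0, 0, 0]])
        table = pair_channels(cap)
        assert len(table) == 1
        assert table.channels[0].separation_mm == pytest.approx(28.0)
        assert (table.channels[0].source, table.channels[0].detector) == \
            ("S1", "D01")

    def test_all_far_apart_empty(self):
        cap = cap_from_coords(
            [[0, 0, 0]], [[41, 0, 0], [0, 45, 0], [0, 0, 50]])
        assert len(pair_channels(cap, 28.0, 0.2)) == 0

    def test_synthetic_cap_23_channels(self, default_cap):
        assert len(pair_channels(default_cap)) == 23

    def test_lexicographic_channel_order(self):
        cap = cap_from_coords([[0, 0, 0], [56, 0, 0]],
                              [[28, 0, 0], [84, 0, 0]])
        table = pair_channels(cap)
        assert [(c.source, c.detector) for c in table] == \
            [("S1", "D01"), ("S2", "D01"), ("S2", "D02")]
        assert table.ids() == ["CH01", "CH02", "CH03"]

    @settings(max_examples=20, deadline=None)
    @given(st.floats(0.05, 0.45), st.floats(0.0, 0.5))
    def test_tolerance_monotonicity(self, tol, extra):
        rng = np.random.default_rng(9)
        cap = cap_from_coords(rng.normal(scale=30, size=(4, 3)),
                              rng.normal(scale=30, size=(8, 3)))
        narrow = {(c.source, c.detector) for c in pair_channels(cap, 28, tol)}
        wide_tol = min(tol + extra, 0.99)
        wide = {(c.source, c.detector)
                for c in pair_channels(cap, 28, wide_tol)}
        assert narrow <= wide

    def test_duplicate_pair_rejected(self):
        from optoreg.cortical_projection import Channel
        with pytest.raises(ValidationError, match="duplicate"):
            ChannelTable([Channel("CH01", "S1", "D01", 28.0),
                          Channel("CH02", "S1", "D01", 28.0)])

    def test_pairing_override_file(self, tmp_path):
        cap = cap_from_coords([[0, 0, 0]], [[40, 0, 0]])
        path = tmp_path / "pairs.csv"
        path.write_text("channel,source,detector\nCH_A,S1,D01\n")
        table = pair_channels_from_file(cap, path)
        assert table.ids() == ["CH_A"]
        assert table.channels[0].separation_mm == pytest.approx(40.0)


class TestChannelMidpoints:
    def test_scalp_midpoint(self):
        cap = cap_from_coords([[0, 0, 0]], [[2.0, 0, 0]])
        table = pair_channels(cap, 2.0, 0.2)
        mids = channel_midpoints(table, cap.to_point_table(), "scalp")
        np.testing.assert_allclose(mids.coords[0], [1, 0, 0])

    def test_coincident_endpoints(self):
        from optoreg.cortical_projection import Channel
        table = ChannelTable([Channel("CH01", "S1", "D01", 1.0)])
        positions = PointTable(["S1", "D01"], [[3, 4, 5], [3, 4, 5]], MNI)
        mids = channel_midpoints(table, positions, "scalp")
        np.testing.assert_allclose(mids.coords[0], [3, 4, 5])

    def test_sphere_reprojection(self):
        """Cortical midpoints land on the cortex mesh; the radius matches the
        analytic sphere up to the mesh's chordal sag."""
        verts, faces = icosphere(4)
        sphere = SurfaceMesh(80.0 * verts, faces, MNI)
        a = 80.0 * verts[10]
        b = 80.0 * verts[11]
        positions = PointTable(["S1", "D01"], [a, b], MNI)
        from optoreg.cortical_projection import Channel
        table = ChannelTable([
            Channel("CH01", "S1", "D01", float(np.linalg.norm(a - b)))])
        mids = channel_midpoints(table, positions, "cortical", sphere)
        # exactly on the mesh (re-projection is a fixed point)
        again = project_to_surface(mids, sphere)
        assert np.abs(again.points.coords - mids.coords).max() < 1e-9
        # and on the analytic sphere up to discretisation (< 0.1 mm at level 4)
        assert abs(np.linalg.norm(mids.coords[0]) - 80.0) < 0.1

    def test_mean_of_projected_mode(self, unit_sphere_head):
        positions = PointTable(["S1", "D01"],
                               [[0, 0, 2.0], [0, 2.0, 0]], MNI)
        from optoreg.cortical_projection import Channel
        table = ChannelTable([Channel("CH01", "S1", "D01", 1.0)])
        mids = channel_midpoints(table, positions, "cortical",
                                 unit_sphere_head.cortex,
                                 midpoint_mode="mean-of-projected")
        assert abs(np.linalg.norm(mids.coords[0]) - 0.8) < 0.05

    def test_missing_optode_id(self):
        from optoreg.cortical_projection import Channel
        table = ChannelTable([Channel("CH01", "S1", "D99", 1.0)])
        positions = PointTable(["S1", "D01"], [[0, 0, 0], [1, 0, 0]], MNI)
        with pytest.raises(ValueError):
            channel_midpoints(table, positions, "scalp")

    def test_attach_midpoints_csv(self, tmp_path, default_cap, default_head):
        table = pair_channels(default_cap)
        mids = channel_midpoints(table, default_cap.to_point_table(),
                                 "cortical", default_head.cortex)
        out = attach_midpoints(table, mids)
        path = out.to_csv(tmp_path / "channels.csv", {"space": "cortical"})
        text = path.read_text()
        assert text.startswith("# space: cortical")
        assert text.count("CH") == 23
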