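"""Geometry, distance and weight-matrix operations."""

import itertools
import math

import numpy as np
import pytest

from fcaccess.core import (
    PointLocation,
    StreetNetwork,
    catchment_members,
    euclidean_distance_matrix,
    inverse_distance_squared_weights,
    queen_contiguity,
    shortest_path_distance_matrix,
)

from conftest import grid_zones

P = PointLocation


class TestEuclidean:
    def test_three_four_five(self):
        dm = euclidean_distance_matrix([P(0, 0)], [P(3, 4)])
        assert dm.values[0, 0] == 5.0

    def test_identity_is_zero(self):
        dm = euclidean_distance_matrix([P(2.5, -1)], [P(2.5, -1)])
        assert dm.values[0, 0] == 0.0

    def test_matches_loop_oracle(self, rng):
        o = [P(*rng.uniform(0, 100, 2)) for _ in range(5)]
        d = [P(*rng.uniform(0, 100, 2)) for _ in range(4)]
        dm = euclidean_distance_matrix(o, d)
        for i, j in itertools.product(range(5), range(4)):
            assert dm.values[i, j] == pytest.approx(
                math.hypot(o[i].x - d[j].x, o[i].y - d[j].y), abs=1e-12
            )

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            euclidean_distance_matrix([], [P(0, 0)])

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            P(math.nan, 0)


class TestNetworkDistance:
    def test_single_edge(self):
        net = StreetNetwork({"a": P(0, 0), "b": P(7, 0)}, [("a", "b", 7.0)])
        dm = shortest_path_distance_matrix(net, [P(0, 0)], [P(7, 0)])
        assert dm.values[0, 0] == 7.0
        assert dm.metric == "network"

    def test_triangle_takes_two_short_edges(self):
        # direct edge costs 3; the detour through the apex costs 1 + 1
        net = StreetNetwork(
            {"a": P(0, 0), "b": P(3, 0), "c": P(1.5, 1)},
            [("a", "b", 3.0), ("a", "c", 1.0), ("c", "b", 1.0)],
        )
        dm = shortest_path_distance_matrix(net, [P(0, 0)], [P(3, 0)])
        assert dm.values[0, 0] == 2.0

    def test_disconnected_is_infinite(self):
        net = StreetNetwork(
            {"a": P(0, 0), "b": P(1, 0), "c": P(10, 0), "d": P(11, 0)},
            [("a", "b", 1.0), ("c", "d", 1.0)],
        )
        dm = shortest_path_distance_matrix(net, [P(0, 0)], [P(11, 0)])
        assert np.isinf(dm.values[0, 0])

    def test_negative_edge_rejected(self):
        with pytest.raises(ValueError):
            StreetNetwork({"a": P(0, 0), "b": P(1, 0)}, [("a", "b", -1.0)])

    def test_empty_network_rejected(self):
        with pytest.raises(ValueError):
            StreetNetwork({}, [])

    def test_dijkstra_equals_path_enumeration(self, rng):
        """On graphs small enough to enumerate every simple path."""
        import networkx as nx

        for trial in range(10):
            n = int(rng.integers(4, 9))
            pts = {f"n{i}": P(*rng.uniform(0, 10, 2)) for i in range(n)}
            ids = list(pts)
            edges = []
            for i in range(1, n):  # random spanning tree keeps it connected
                j = int(rng.integers(0, i))
                edges.append((ids[i], ids[j], float(rng.uniform(0.1, 5))))
            for _ in range(n):
                i, j = rng.integers(0, n, 2)
                if i != j:
                    edges.append((ids[i], ids[j], float(rng.uniform(0.1, 5))))
            net = StreetNetwork(pts, edges)
            src, dst = pts[ids[0]], pts[ids[-1]]
            dm = shortest_path_distance_matrix(net, [src], [dst])
            best = min(
                sum(
                    net.graph[u][v]["length"]
                    for u, v in zip(path, path[1:])
                )
                for path in nx.all_simple_paths(net.graph, ids[0], ids[-1])
            )
            assert dm.values[0, 0] == pytest.approx(best, rel=1e-12)

    def test_network_at_least_euclidean_on_grid(self):
        """With edge lengths equal to endpoint spacing, paths can't beat lines."""
        nodes = {f"{i}_{j}": P(i * 100.0, j * 100.0) for i in range(4) for j in range(4)}
        edges = []
        for i in range(4):
            for j in range(4):
                if i + 1 < 4:
                    edges.append((f"{i}_{j}", f"{i+1}_{j}", 100.0))
                if j + 1 < 4:
                    edges.append((f"{i}_{j}", f"{i}_{j+1}", 100.0))
        net = StreetNetwork(nodes, edges)
        pts = list(nodes.values())
        net_dm = shortest_path_distance_matrix(net, pts, pts)
        euc_dm = euclidean_distance_matrix(pts, pts)
        assert np.all(net_dm.values >= euc_dm.values - 1e-9)

    def test_snap_tie_breaks_to_lowest_node_id(self):
        net = StreetNetwork(
            {"a": P(0, 0), "b": P(2, 0)}, [("a", "b", 2.0)]
        )
        assert net.snap([P(1, 0)]) == ["a"]


class TestCatchments:
    def test_threshold_is_inclusive(self):
        # distances [[400], [700]]: only the first zone is within 500 m
        dm = euclidean_distance_matrix([P(0, 0), P(0, 1100)], [P(0, 400)])
        m = catchment_members(dm, 500.0)
        assert m["by_destination"][0] == [0]
        m2 = catchment_members(dm, 400.0)  # exactly d0 is still a member
        assert m2["by_destination"][0] == [0]

    def test_saturation_when_threshold_exceeds_max(self, rng):
        dm = euclidean_distance_matrix(
            [P(*rng.uniform(0, 10, 2)) for _ in range(5)],
            [P(*rng.uniform(0, 10, 2)) for _ in range(3)],
        )
        m = catchment_members(dm, dm.values.max() + 1)
        assert all(len(v) == 5 for v in m["by_destination"].values())

    def test_matches_loop_filter_oracle(self, rng):
        dm = euclidean_distance_matrix(
            [P(*rng.uniform(0, 100, 2)) for _ in range(20)],
            [P(*rng.uniform(0, 100, 2)) for _ in range(10)],
        )
        d0 = float(np.median(dm.values))
        m = catchment_members(dm, d0)
        for j in range(10):
            expected = [i for i in range(20) if dm.values[i, j] <= d0]
            assert m["by_destination"][j] == expected
        for i in range(20):
            expected = [j for j in range(10) if dm.values[i, j] <= d0]
            assert m["by_origin"][i] == expected

    def test_membership_monotone_in_threshold(self, rng):
        dm = euclidean_distance_matrix(
            [P(*rng.uniform(0, 100, 2)) for _ in range(12)],
            [P(*rng.uniform(0, 100, 2)) for _ in range(6)],
        )
        thresholds = sorted(rng.uniform(5, 150, 4))
        prev = None
        for d0 in thresholds:
            cur = {
                j: set(v) for j, v in catchment_members(dm, d0)["by_destination"].items()
            }
            if prev is not None:
                assert all(prev[j] <= cur[j] for j in cur)
            prev = cur

    def test_nonpositive_threshold_rejected(self):
        dm = euclidean_distance_matrix([P(0, 0)], [P(1, 0)])
        with pytest.raises(ValueError):
            catchment_members(dm, 0)


class TestQueenContiguity:
    def test_shared_edge(self):
        w = queen_contiguity(grid_zones(1, 2))
        assert w.dense.tolist() == [[0, 1], [1, 0]]

    def test_corner_touch_counts(self):
        # diagonal cells of a 2x2 grid touch only at the corner
        zones = grid_zones(2, 2)
        w = queen_contiguity([zones[0], zones[3]])
        assert w.dense[0, 1] == 1

    def test_center_of_3x3_has_eight_neighbours(self):
        w = queen_contiguity(grid_zones(3, 3))
        center = 4
        assert w.dense[center].sum() == 8

    def test_symmetric_with_grid_oracle(self):
        rows, cols = 4, 5
        w = queen_contiguity(grid_zones(rows, cols)).dense
        assert np.array_equal(w, w.T)
        for i in range(rows * cols):
            r_i, c_i = divmod(i, cols)
            for j in range(rows * cols):
                r_j, c_j = divmod(j, cols)
                adjacent = i != j and abs(r_i - r_j) <= 1 and abs(c_i - c_j) <= 1
                assert w[i, j] == (1 if adjacent else 0)

    def test_missing_polygon_rejected(self):
        from fcaccess.core import Zone

        z = Zone(id="z", centroid=P(0, 0))
        with pytest.raises(ValueError):
            queen_contiguity([z])


class TestInverseDistanceSquared:
    def test_two_points_two_meters_apart(self):
        w = inverse_distance_squared_weights([P(0, 0), P(2, 0)])
        assert w.dense[0, 1] == 0.25
        assert w.dense[0, 0] == 0

    def test_scaling_homogeneity(self, rng):
        pts = [P(*rng.uniform(0, 10, 2)) for _ in range(5)]
        scaled = [P(3 * p.x, 3 * p.y) for p in pts]
        w1 = inverse_distance_squared_weights(pts).dense
        w2 = inverse_distance_squared_weights(scaled).dense
        np.testing.assert_allclose(w2, w1 / 9.0, rtol=1e-12)

    def test_matches_loop_oracle(self, rng):
        pts = [P(*rng.uniform(0, 50, 2)) for _ in range(6)]
        w = inverse_distance_squared_weights(pts).dense
        for i in range(6):
            for j in range(6):
                if i == j:
                    assert w[i, j] == 0
                else:
                    d2 = (pts[i].x - pts[j].x) ** 2 + (pts[i].y - pts[j].y) ** 2
                    assert w[i, j] == pytest.approx(1 / d2, rel=1e-12)

    def test_coincident_centroids_named(self):
        with pytest.raises(ValueError, match="0 and 2"):
            inverse_distance_squared_weights([P(0, 0), P(1, 1), P(0, 0)])
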