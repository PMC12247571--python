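"""Relative thresholding, 6-D clustering, connection scoring, FROC."""

import numpy as np
import pytest

from beamcoh import detect
from beamcoh.forward import SourceGrid


def make_grid(side=6, spacing=0.01):
    idx = np.array(
        [(i, j, k) for i in range(side) for j in range(side) for k in range(side)]
    )
    return SourceGrid(
        positions=(idx + 0.5) * spacing, spacing=spacing, lattice_indices=idx
    )


def brute_force_clusters(edges, grid):
    """O(E^2) union-find oracle for the 6-D edge adjacency rule."""
    eps = 1e-9
    step = grid.spacing * np.sqrt(3) + eps
    pos = grid.positions
    pairs = edges.pairs
    parent = list(range(len(pairs)))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(x, y):
        parent[find(x)] = find(y)

    def near(a, b):
        return np.linalg.norm(pos[a] - pos[b]) <= step

    for e in range(len(pairs)):
        for f in range(e + 1, len(pairs)):
            (i, j), (k, l) = pairs[e], pairs[f]
            if (near(i, k) and near(j, l)) or (near(i, l) and near(j, k)):
                union(e, f)
    groups = {}
    for e in range(len(pairs)):
        groups.setdefault(find(e), []).append(tuple(sorted(pairs[e])))
    return {frozenset(v) for v in groups.values()}


class TestEdgeCounts:
    @pytest.mark.parametrize(
        "pct,expected",
        [(0.005, 975), (0.001, 195), (0.0005, 98), (0.01, 1950)],
    )
    def test_relative_threshold_ladder_4416(self, pct, expected):
        assert detect.edge_count(pct, 4416) == expected

    def test_round_half_up(self):
        # 0.0005% of 4416^2 = 97.505... -> 98
        assert detect.edge_count(0.0005, 4416) == 98

    def test_invalid_pct(self):
        with pytest.raises(ValueError):
            detect.edge_count(0.0, 100)


class TestThresholdEdges:
    def test_single_largest_entry(self):
        vol = np.array([[0, 1.0, 2.0], [1.0, 0, 5.0], [2.0, 5.0, 0]])
        es = detect.threshold_edges(vol, 100 / 9)  # keeps round(9 * 1/9) = 1
        assert es.count == 1
        np.testing.assert_array_equal(es.pairs[0], [1, 2])

    def test_counts_on_large_symmetric_volume(self, rng):
        n = 4416
        vol = rng.standard_normal((n, n))
        vol = vol + vol.T
        assert detect.threshold_edges(vol, 0.001).count == 195
        assert detect.threshold_edges(vol, 0.0005).count == 98

    def test_tie_break_lower_flat_index(self):
        vol = np.zeros((4, 4))
        vol[0, 3] = vol[3, 0] = 1.0
        vol[1, 2] = vol[2, 1] = 1.0
        es = detect.threshold_edges(vol, 100 * 1 / 16)  # 1 edge, tied values
        np.testing.assert_array_equal(es.pairs[0], [0, 3])  # flat (0,3) < (1,2)

    def test_nesting_across_ladder(self, rng):
        vol = rng.standard_normal((100, 100))
        vol = vol + vol.T
        prev = None
        for pct in detect.DEFAULT_THRESHOLDS:  # descending pct
            cur = {tuple(p) for p in detect.threshold_edges(vol, pct).pairs}
            if prev is not None:
                assert cur <= prev
            prev = cur

    def test_invalid_entries_excluded(self):
        vol = np.full((3, 3), np.nan)
        vol[0, 1] = vol[1, 0] = 1.0
        es = detect.threshold_edges(vol, 50.0)
        np.testing.assert_array_equal(es.pairs, [[0, 1]])

    def test_empty_volume_raises(self):
        with pytest.raises(ValueError):
            detect.threshold_edges(np.empty((0, 0)), 1.0)


class TestClustering:
    def test_single_edge_single_cluster(self):
        grid = make_grid()
        es = detect.EdgeSet(
            pairs=np.array([[0, 100]]), values=np.ones(1), pct=1.0, n_dipoles=216
        )
        clusters = detect.cluster_edges_6d(es, grid)
        assert len(clusters) == 1
        np.testing.assert_array_equal(clusters[0].assembly_a, [0])
        np.testing.assert_array_equal(clusters[0].assembly_b, [100])

    def test_shared_endpoint_one_step_apart_merges(self):
        grid = make_grid()
        # endpoints 100 and 101 differ by one z-step -> adjacent edges
        es = detect.EdgeSet(
            pairs=np.array([[0, 100], [0, 101]]),
            values=np.ones(2),
            pct=1.0,
            n_dipoles=216,
        )
        assert len(detect.cluster_edges_6d(es, grid)) == 1

    def test_distant_edges_stay_separate(self):
        grid = make_grid()
        # (0,0,0)-(0,0,5) vs (5,5,0)-(5,5,5): endpoints 5 steps apart
        a = grid.lattice_indices.tolist()
        i1, j1 = a.index([0, 0, 0]), a.index([0, 0, 5])
        i2, j2 = a.index([5, 5, 0]), a.index([5, 5, 5])
        es = detect.EdgeSet(
            pairs=np.array([[i1, j1], [i2, j2]]),
            values=np.ones(2),
            pct=1.0,
            n_dipoles=216,
        )
        assert len(detect.cluster_edges_6d(es, grid)) == 2

    def test_swapped_orientation_adjacency(self):
        grid = make_grid()
        a = grid.lattice_indices.tolist()
        p = a.index([0, 0, 0])
        q = a.index([5, 5, 5])
        q2 = a.index([5, 5, 4])
        # edges (p, q) and (q2, p): adjacent only via the swapped pairing
        es = detect.EdgeSet(
            pairs=np.array([[p, q], [min(q2, p), max(q2, p)]]),
            values=np.ones(2),
            pct=1.0,
            n_dipoles=216,
        )
        clusters = detect.cluster_edges_6d(es, grid)
        assert len(clusters) == 1
        c = clusters[0]
        assert set(c.assembly_a) == {p} and set(c.assembly_b) == {q, q2}

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_matches_brute_force_union_find(self, seed):
        grid = make_grid(side=7)
        rng = np.random.default_rng(seed)
        n = grid.n_sources
        k = 150
        iu, ju = np.triu_indices(n, 1)
        sel = rng.choice(iu.size, k, replace=False)
        es = detect.EdgeSet(
            pairs=np.column_stack([iu[sel], ju[sel]]),
            values=rng.uniform(size=k),
            pct=1.0,
            n_dipoles=n,
        )
        got = {
            frozenset(tuple(sorted(e)) for e in map(tuple, c.edges))
            for c in detect.cluster_edges_6d(es, grid)
        }
        assert got == brute_force_clusters(es, grid)


class TestFilterAndScore:
    def _cluster(self, a, b):
        return detect.Cluster(
            edges=np.array([[x, y] for x in a for y in b]),
            assembly_a=np.array(a),
            assembly_b=np.array(b),
        )

    def test_auto_connection_discarded(self):
        mixed = [
            self._cluster([0, 1], [1, 2]),  # shares dipole 1 -> auto
            self._cluster([0], [50]),
            self._cluster([10, 11], [60]),
        ]
        kept = detect.filter_clusters(mixed)
        assert len(kept) == 2
        assert all(not c.is_auto_connection for c in kept)

    def test_exact_hit_no_false_positives(self):
        grid = make_grid()
        conn = [self._cluster([0], [100])]
        hit, fp = detect.score_detection(
            conn, grid.positions[[0, 100]], grid.positions
        )
        assert hit and fp == 0

    def test_no_connections_is_miss(self):
        grid = make_grid()
        hit, fp = detect.score_detection([], grid.positions[[0, 100]], grid.positions)
        assert not hit and fp == 0

    def test_one_match_two_distant(self):
        grid = make_grid()
        a = grid.lattice_indices.tolist()
        far1 = a.index([5, 5, 5])
        far2 = a.index([5, 0, 5])
        conns = [
            self._cluster([0], [100]),
            self._cluster([far1], [far2]),
            self._cluster([far2], [far1]),
        ]
        hit, fp = detect.score_detection(
            conns, grid.positions[[0, 100]], grid.positions
        )
        assert hit and fp == 2

    def test_assembly_pairing_is_symmetric(self):
        grid = make_grid()
        conn = [self._cluster([100], [0])]  # swapped relative to truth order
        hit, _ = detect.score_detection(
            conn, grid.positions[[0, 100]], grid.positions
        )
        assert hit

    def test_near_active_false_positive(self):
        grid = make_grid()
        active = grid.positions[[0, 100, 215]]
        conn_near = [self._cluster([0], [100])]
        assert detect.near_active_false_positive(conn_near, active, grid.positions)
        # pick two voxels each > 2 cm from every active dipole
        d_active = np.linalg.norm(
            grid.positions[:, None, :] - active[None, :, :], axis=2
        ).min(axis=1)
        far = np.nonzero(d_active > 0.021)[0][:2]
        conn_far = [self._cluster([far[0]], [far[1]])]
        assert not detect.near_active_false_positive(conn_far, active, grid.positions)


class TestFROC:
    def test_all_hits_no_false_positives(self):
        records = [
            {"pct": p, "hit": True, "n_false_positives": 0}
            for p in (0.01, 0.005)
            for _ in range(4)
        ]
        t = detect.froc(records)
        assert (t.hit_rate == 1.0).all()
        assert (t.mean_false_positives == 0.0).all()

    def test_hand_computed_means(self):
        records = [
            {"pct": 0.01, "hit": True, "n_false_positives": 4},
            {"pct": 0.01, "hit": False, "n_false_positives": 2},
            {"pct": 0.001, "hit": False, "n_false_positives": 1},
            {"pct": 0.001, "hit": False, "n_false_positives": 0},
        ]
        t = detect.froc(records).set_index("pct")
        assert t.loc[0.01, "hit_rate"] == pytest.approx(0.5)
        assert t.loc[0.01, "mean_false_positives"] == pytest.approx(3.0)
        assert t.loc[0.001, "hit_rate"] == 0.0
        assert t.loc[0.001, "mean_false_positives"] == pytest.approx(0.5)

    def test_edge_budget_monotone_in_pct(self, rng):
        # nesting of edge sets implies the number of suprathreshold edges
        # (and hence potential false positives) grows with pct
        vol = rng.standard_normal((50, 50))
        vol = vol + vol.T
        counts = [
            detect.threshold_edges(vol, p).count
            for p in sorted(detect.DEFAULT_THRESHOLDS)
        ]
        assert counts == sorted(counts)
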