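"""Matching, registration, distance matrix, matching tree, propagation."""

import numpy as np
import pytest

from berrytrack.features import BerryObservation
from berrytrack.geometry import Ellipse
from berrytrack.tracking import (AffineCPD, DELTA, FrameSet, THETA,
                                 build_distance_matrix, build_matching_tree,
                                 chain_tree, greedy_match, propagate_labels,
                                 register_affine, select_root, set_distance_d,
                                 symmetric_distance_D, track)


def greedy_oracle(a, b, delta=DELTA):
    """Independent statement of the greedy rule: repeatedly admit the
    globally closest unused pair (ties: lowest a then b index) while the
    distance stays within delta."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    pairs = []
    used_a, used_b = set(), set()
    while True:
        best = None
        for i in range(len(a)):
            if i in used_a:
                continue
            for j in range(len(b)):
                if j in used_b:
                    continue
                d = float(np.hypot(*(a[i] - b[j])))
                if best is None or d < best[0] - 1e-12:
                    best = (d, i, j)
        if best is None or best[0] > delta:
            return pairs
        _, i, j = best
        used_a.add(i)
        used_b.add(j)
        pairs.append((i, j))


def make_series(point_sets, times=None):
    series = []
    for t, pts in enumerate(point_sets):
        obs = [BerryObservation(frame=t, time=(times[t] if times else t / 3.0),
                                ellipse=Ellipse(x, y, 10, 12, 0), score=1.0)
               for x, y in pts]
        series.append(FrameSet(t=t, observations=obs,
                               time_days=times[t] if times else t / 3.0))
    return series


class TestGreedyMatch:
    def test_identity(self):
        pts = [(0, 0), (30, 0), (0, 30)]
        assert greedy_match(pts, pts) == [(0, 0), (1, 1), (2, 2)]

    def test_delta_threshold(self):
        assert greedy_match([(0, 0)], [(20, 0)]) == []
        assert greedy_match([(0, 0)], [(16, 0)]) == [(0, 0)]
        assert DELTA == 16.0

    def test_consumed_point_blocks_second_match(self):
        assert greedy_match([(0, 0), (10, 0)], [(1, 0)]) == [(0, 0)]

    def test_agrees_with_oracle_on_random_instances(self, rng):
        for _ in range(200):
            na, nb = rng.integers(0, 9, 2)
            a = rng.uniform(0, 60, (na, 2))
            b = rng.uniform(0, 60, (nb, 2))
            assert greedy_match(a, b) == greedy_oracle(a, b)


class TestRegisterAffine:
    def test_identity_on_equal_sets(self, rng):
        pts = rng.uniform(0, 500, (40, 2))
        moved, (B, t), _ = register_affine(pts, pts)
        assert np.allclose(moved, pts, atol=1e-6)

    def test_recovers_known_affine(self, rng):
        pts = rng.uniform(0, 500, (50, 2))
        th = np.deg2rad(10)
        R = 1.05 * np.array([[np.cos(th), -np.sin(th)],
                             [np.sin(th), np.cos(th)]])
        moved_truth = pts @ R.T + [20, -10]
        back, _, converged = register_affine(pts, moved_truth)
        assert converged
        assert symmetric_distance_D(pts, back) < 0.5

    def test_robust_to_spurious_points(self, rng):
        pts = rng.uniform(0, 500, (50, 2))
        th = np.deg2rad(8)
        R = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        moved = np.vstack([pts @ R.T + [15, 5], rng.uniform(0, 500, (5, 2))])
        back, _, _ = register_affine(pts, moved)
        assert set_distance_d(pts, back) < 2.0

    def test_small_sets_returned_unchanged(self):
        ref = np.array([[0.0, 0], [10, 0], [0, 10]])
        mov = np.array([[5.0, 5], [15, 5]])
        back, (B, t), _ = register_affine(ref, mov)
        assert np.array_equal(back, mov)
        assert np.array_equal(B, np.eye(2))

    def test_registration_never_increases_distance_under_affine_motion(
            self, scenario_runs):
        """On affine-jitter data, registering before measuring D can only
        help (up to numerical tolerance)."""
        series = scenario_runs["nominal_jitter"]["series"]
        rng = np.random.default_rng(0)
        for _ in range(20):
            i, j = rng.integers(0, len(series), 2)
            if i == j:
                continue
            a, b = series[i].points, series[j].points
            moved, _, _ = register_affine(a, b)
            assert symmetric_distance_D(a, moved) <= \
                symmetric_distance_D(a, b) + 0.1


class TestSetDistances:
    def test_identical_sets_zero(self, rng):
        pts = rng.uniform(0, 100, (20, 2))
        assert set_distance_d(pts, pts) == 0.0
        assert symmetric_distance_D(pts, pts) == 0.0

    def test_pure_translation(self):
        a = np.array([[0.0, 0], [50, 0], [0, 50], [50, 50]])
        b = a + [3.0, 4.0]
        assert set_distance_d(a, b) == pytest.approx(5.0)

    def test_asymmetry_and_symmetrization(self):
        a = np.array([[0.0, 0]])
        b = np.array([[0.0, 0], [100.0, 0]])
        assert set_distance_d(a, b) == 0.0
        assert set_distance_d(b, a) == pytest.approx(50.0)  # even-count median
        assert symmetric_distance_D(a, b) == pytest.approx(25.0)
        assert symmetric_distance_D(b, a) == pytest.approx(25.0)

    def test_empty_set_raises(self):
        with pytest.raises(ValueError):
            set_distance_d(np.empty((0, 2)), np.array([[0.0, 0]]))


class TestDistanceMatrix:
    def test_static_series_all_zero(self):
        pts = [[(0, 0), (40, 0), (0, 40), (40, 40)]] * 4
        M = build_distance_matrix(make_series(pts))
        assert np.allclose(M, 0.0, atol=1e-6)

    def test_rigid_rotation_absorbed(self, scenario_runs):
        M = scenario_runs["rigid_rotation_event"]["matrix"]
        assert np.nanmax(M) < THETA  # registration absorbs the rotation

    def test_nonaffine_break_block_structure(self, scenario_runs):
        M = scenario_runs["nonaffine_break"]["matrix"]
        k = 30  # shuffle frame of the scenario
        within = np.r_[M[:k, :k][np.triu_indices(k, 1)],
                       M[k:, k:][np.triu_indices(M.shape[0] - k, 1)]]
        across = M[:k, k:].ravel()
        assert within.max() < THETA
        assert np.median(across) > 5 * THETA


class TestMatchingTree:
    def test_single_frame(self):
        tree = build_matching_tree(np.zeros((1, 1)), root=0)
        assert tree.root == 0 and tree.parent == {} and tree.depth == {0: 0}

    def test_three_close_frames_star(self):
        M = np.full((3, 3), 1.0)
        np.fill_diagonal(M, 0.0)
        tree = build_matching_tree(M, root=0)
        assert tree.parent == {1: 0, 2: 0}
        assert tree.long_distance == set()

    def test_three_far_frames_chain_of_long_edges(self):
        M = np.full((3, 3), 100.0)
        np.fill_diagonal(M, 0.0)
        tree = build_matching_tree(M, root=0)
        assert tree.parent == {1: 0, 2: 1}
        assert tree.long_distance == {(0, 1), (1, 2)}

    def test_spans_and_depth_consistent(self, scenario_runs):
        for name in ["nominal_jitter", "nonaffine_break"]:
            tree = scenario_runs[name]["tree"]
            n = scenario_runs[name]["matrix"].shape[0]
            assert set(tree.depth) == set(range(n))
            assert tree.depth[tree.root] == 0
            for child, par in tree.parent.items():
                assert tree.depth[child] == tree.depth[par] + 1

    def test_long_distance_edge_count_on_break(self, scenario_runs):
        assert len(scenario_runs["nonaffine_break"]["tree"].long_distance) == 1


class TestSelectRoot:
    def test_all_close_picks_largest_frame(self):
        M = np.full((3, 3), 1.0)
        np.fill_diagonal(M, 0.0)
        assert select_root(M, [5, 9, 7]) == 1

    def test_root_in_larger_consistent_block(self):
        n1, n2 = 8, 5
        n = n1 + n2
        M = np.full((n, n), 100.0)
        M[:n1, :n1] = 1.0
        M[n1:, n1:] = 1.0
        np.fill_diagonal(M, 0.0)
        assert select_root(M, [10] * n) < n1

    def test_single_frame(self):
        assert select_root(np.zeros((1, 1)), [4]) == 0


class TestPropagateLabels:
    def test_static_full_coverage(self):
        pts = [[(0, 0), (40, 0), (0, 40)]] * 5
        series = make_series(pts)
        table = propagate_labels(series, chain_tree(5))
        assert table.coverage() == 1.0
        for t in range(5):
            assert sorted(table.labels[t]) == [0, 1, 2]

    def test_occlusion_gap_recovered(self):
        """A berry hidden for 3 frames loses its label only while hidden."""
        base = [(0, 0), (40, 0), (0, 40), (40, 40)]
        pts = []
        for t in range(10):
            pts.append([p for k, p in enumerate(base) if not (k == 2 and 4 <= t <= 6)])
        series = make_series(pts)
        table, tree, _ = track(series)
        # identify the label of berry 2 at root
        root_pts = series[tree.root].points
        lab2 = None
        for k, p in enumerate(root_pts):
            if tuple(p) == (0.0, 40.0):
                lab2 = table.labels[tree.root][k]
        assert lab2 is not None
        for t in range(10):
            fs = series[t]
            has = any(table.labels[t][k] == lab2 for k in range(len(fs)))
            assert has == (not 4 <= t <= 6)

    def test_deterministic(self, scenario_runs):
        r = scenario_runs["nominal_jitter"]
        table2 = propagate_labels(r["series"], r["tree"])
        for t, lab in r["table"].labels.items():
            assert np.array_equal(lab, table2.labels[t])

    def test_nonaffine_break_unlabels_but_does_not_mislabel(self, scenario_runs):
        r = scenario_runs["nonaffine_break"]
        sc = r["score"]
        assert sc.T_c < 70.0      # second half largely unlabeled
        assert sc.T_p >= 95.0     # surviving labels stay essentially pure
        second = np.concatenate([r["table"].labels[t] for t in range(30, 60)])
        assert (second >= 0).mean() < 0.2


class TestTrackEntry:
    def test_requires_two_frames(self):
        with pytest.raises(ValueError):
            track(make_series([[(0, 0)]]))
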