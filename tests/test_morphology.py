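import numpy as np
import pandas as pd
import pytest

import gliawave as gw
from gliawave.morphology import register_stalk_xy, sholl_center

from conftest import star_skeleton


def make_skeleton(rows):
    return gw.Skeleton(
        pd.DataFrame(rows, columns=["node_id", "node_type", "x", "y", "z", "radius", "parent_id"])
    )


class TestSkeletonMetrics:
    def test_bare_stalk_all_zero(self):
        skel = make_skeleton([(1, 2, 0, 0, 0, 1, -1), (2, 2, 0, 0, 10, 1, 1)])
        m = gw.skeleton_metrics(skel)
        assert (m.n_tips, m.n_branch_points, m.n_primary_branches) == (0, 0, 0)
        assert m.total_length_um == 0.0

    def test_three_unbranched_processes(self, example_skeleton):
        m = gw.skeleton_metrics(example_skeleton)
        assert m.n_tips == 3
        assert m.n_primary_branches == 3
        assert m.total_length_um == pytest.approx(15.0)
        assert m.n_branch_points == 0

    def test_binary_tree_depth_two(self):
        rows = [
            (1, 2, 0, 0, 0, 1, -1),
            (2, 2, 0, 0, 5, 1, 1),
            (10, 3, 1, 0, 5, 1, 2),   # primary branch root
            (11, 3, 2, 1, 5, 1, 10),
            (12, 3, 2, -1, 5, 1, 10),
            (13, 3, 3, 2, 5, 1, 11),
            (14, 3, 3, 1, 5, 1, 11),
            (15, 3, 3, -1, 5, 1, 12),
            (16, 3, 3, -2, 5, 1, 12),
        ]
        m = gw.skeleton_metrics(make_skeleton(rows))
        assert m.n_tips == 4
        assert m.n_branch_points == 3
        assert m.n_primary_branches == 1

    def test_untagged_stalk_rejected(self):
        skel = make_skeleton([(1, 3, 0, 0, 0, 1, -1), (2, 3, 1, 0, 0, 1, 1)])
        with pytest.raises(ValueError, match="stalk"):
            gw.skeleton_metrics(skel)

    def test_total_length_invariant_under_rotation(self, example_skeleton):
        theta = 0.7
        rot = np.array(
            [[np.cos(theta), -np.sin(theta), 0], [np.sin(theta), np.cos(theta), 0], [0, 0, 1]]
        )
        nodes = example_skeleton.nodes.copy()
        nodes[["x", "y", "z"]] = nodes[["x", "y", "z"]].to_numpy() @ rot.T
        m0 = gw.skeleton_metrics(example_skeleton)
        m1 = gw.skeleton_metrics(gw.Skeleton(nodes))
        assert m1.total_length_um == pytest.approx(m0.total_length_um)

    def test_metrics_invariant_under_reindexing(self, example_skeleton):
        nodes = example_skeleton.nodes.copy()
        remap = {1: 7, 2: 3, 3: 9, 4: 1, 5: 2, 6: 8}
        nodes["node_id"] = nodes["node_id"].map(remap)
        nodes["parent_id"] = nodes["parent_id"].map(lambda p: -1 if p == -1 else remap[p])
        nodes = nodes.sample(frac=1.0, random_state=0)
        m0 = gw.skeleton_metrics(example_skeleton)
        m1 = gw.skeleton_metrics(gw.Skeleton(nodes))
        assert (m1.n_tips, m1.n_branch_points) == (m0.n_tips, m0.n_branch_points)
        assert m1.total_length_um == pytest.approx(m0.total_length_um)


class TestSholl:
    def test_single_straight_segment_crossings(self):
        skel = make_skeleton([(1, 2, 0, 0, 0, 1, -1), (2, 3, 5, 0, 0, 1, 1)])
        prof = gw.sholl_profile(skel, plane="XY", ring_spacing_um=1.0)
        counts = dict(zip(prof["radius_um"], prof["intersections"]))
        assert [counts.get(float(r), 0) for r in (1, 2, 3, 4)] == [1, 1, 1, 1]
        assert all(v == 0 for r, v in counts.items() if r >= 5)

    @pytest.mark.parametrize("plane", ["XY", "XZ", "YZ"])
    @pytest.mark.parametrize("k", [3, 8])
    def test_star_oracle_all_planes(self, plane, k):
        prof = gw.sholl_profile(star_skeleton(k, spoke_len=5.5, plane=plane), plane=plane)
        below = prof[prof["radius_um"] < 5.5]
        assert len(below) == 5
        assert (below["intersections"] == k).all()
        assert (prof.loc[prof["radius_um"] > 5.5, "intersections"] == 0).all()

    def test_empty_process_set_zero_profile(self):
        skel = make_skeleton([(1, 2, 0, 0, 0, 1, -1), (2, 2, 0, 0, 8, 1, 1)])
        prof = gw.sholl_profile(skel, plane="XY")
        assert (prof["intersections"] == 0).all()

    def test_normalized_radii_and_resampling(self):
        skel = star_skeleton(4, spoke_len=5.0)
        prof = gw.sholl_profile(skel, normalize_to_ipl=True, ipl_thickness_um=10.0)
        assert prof["radius_norm"].max() <= 1.0
        grid = gw.resample_normalized_sholl(prof)
        assert len(grid) == 101
        assert grid.loc[np.isclose(grid["radius_norm"], 0.3), "intersections"].iloc[0] > 0

    def test_zero_ipl_thickness_rejected(self):
        with pytest.raises(ValueError, match="ipl"):
            gw.sholl_profile(star_skeleton(3), normalize_to_ipl=True, ipl_thickness_um=0.0)

    def test_xz_center_is_inl_end_of_stalk(self):
        rows = [
            (1, 2, 1.0, 2.0, 0.0, 1, -1),
            (2, 2, 1.5, 2.0, 10.0, 1, 1),
            (3, 3, 4.0, 2.0, 3.0, 1, 2),
        ]
        skel = make_skeleton(rows)
        np.testing.assert_allclose(sholl_center(skel, "XZ"), [1.0, 0.0])
        np.testing.assert_allclose(register_stalk_xy(skel), [1.25, 2.0])


class TestConvexHull:
    def test_square_outline(self):
        rows = [
            (1, 2, 0, 0, 0, 1, -1),
            (2, 3, 10, 0, 0, 1, 1),
            (3, 3, 10, 10, 0, 1, 2),
            (4, 3, 0, 10, 0, 1, 3),
        ]
        assert gw.convex_hull_area(make_skeleton(rows)) == pytest.approx(100.0)

    def test_single_segment_degenerate(self):
        skel = make_skeleton([(1, 2, 0, 0, 0, 1, -1), (2, 3, 5, 0, 0, 1, 1)])
        with pytest.warns(UserWarning, match="degenerate|collinear"):
            assert gw.convex_hull_area(skel) == 0.0

    def test_matches_brute_force_hull(self):
        # O(n^3) oracle: sum of fan triangle areas over orientation-filtered hull
        rng = np.random.default_rng(17)
        for trial in range(5):
            pts = rng.uniform(0, 20, size=(12, 2))
            rows = [(1, 2, pts[0, 0], pts[0, 1], 0.0, 1, -1)]
            rows += [
                (i + 2, 3, pts[i + 1, 0], pts[i + 1, 1], 0.0, 1, 1)
                for i in range(len(pts) - 1)
            ]
            area = gw.convex_hull_area(make_skeleton(rows))
            # brute-force hull: point on hull iff it is a vertex of some empty
            # half-plane; build via gift wrapping over all point pairs
            hull_pts = _gift_wrap(pts)
            brute = 0.0
            for i in range(1, len(hull_pts) - 1):
                a, b, c = hull_pts[0], hull_pts[i], hull_pts[i + 1]
                brute += 0.5 * abs(
                    (b[0] - a[0]) * (c[1] - a[1]) - (c[0] - a[0]) * (b[1] - a[1])
                )
            assert area == pytest.approx(brute, rel=1e-9)


def _gift_wrap(pts):
    start = min(range(len(pts)), key=lambda i: (pts[i][0], pts[i][1]))
    hull = [start]
    while True:
        cur = hull[-1]
        cand = (cur + 1) % len(pts)
        for j in range(len(pts)):
            if j == cur:
                continue
            cross = (pts[cand][0] - pts[cur][0]) * (pts[j][1] - pts[cur][1]) - (
                pts[j][0] - pts[cur][0]
            ) * (pts[cand][1] - pts[cur][1])
            if cross < 0:
                cand = j
        if cand == start:
            break
        hull.append(cand)
    return [pts[i] for i in hull]


class TestSublayers:
    def test_tip_exactly_at_inl_border_in_s1(self):
        counts = gw.sublayer_distribution([0.0], (0.0, 30.0))
        assert counts["S1"] == 1

    def test_one_tip_per_sublayer(self):
        depths = np.array([0.1, 0.3, 0.5, 0.7, 0.9]) * 30.0
        counts = gw.sublayer_distribution(depths, (0.0, 30.0))
        assert counts.tolist() == [1, 1, 1, 1, 1]

    def test_gcl_border_in_s5(self):
        counts = gw.sublayer_distribution([30.0], (0.0, 30.0))
        assert counts["S5"] == 1

    def test_outside_tips_dropped_with_warning(self):
        with pytest.warns(UserWarning, match="outside"):
            counts = gw.sublayer_distribution([-1.0, 15.0, 40.0], (0.0, 30.0))
        assert counts.sum() == 1

    def test_inverted_bounds_rejected(self):
        with pytest.raises(ValueError, match="[Ii]nverted"):
            gw.sublayer_distribution([5.0], (30.0, 0.0))

    def test_uniform_depths_near_equal_counts(self):
        rng = np.random.default_rng(8)
        depths = rng.uniform(0.0, 30.0, size=10_000)
        counts = gw.sublayer_distribution(depths, (0.0, 30.0))
        assert counts.sum() == 10_000
        # simultaneous check over the 5 bins: chi-square against uniform
        res = gw.chisq_goodness_of_fit(counts.to_numpy())
        assert res.p_value > 1e-6
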