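"""Spine taxonomy, interaction scoring, arbor analysis — checked against
closed forms and brute-force oracles."""

import itertools

import numpy as np
import pandas as pd
import pytest

from miaglia import morphometry as morph


def _trace(rows):
    """rows: (node_id, type, x, y, z, parent)."""
    df = pd.DataFrame(rows, columns=["node_id", "type", "x", "y", "z", "parent"])
    df["radius"] = 0.5
    return morph.MicrogliaTrace(df)


class TestClassifySpine:
    @pytest.mark.parametrize(
        "neck,head,expected",
        [
            (0.0, 0.5, "stubby"),
            (0.0, 0.0, "stubby"),
            (1.0, 0.8, "mushroom"),
            (4.0, 0.7, "mushroom"),  # head rule precedes neck-length rule
            (3.5, 0.3, "filopodia"),
            (1.0, 0.3, "thin"),
            (2.9, 0.05, "thin"),
        ],
    )
    def test_printed_rules(self, neck, head, expected):
        assert morph.classify_spine(neck, head) == expected

    def test_exhaustive_grid_is_partition(self):
        """Every (neck, head) point gets exactly one subtype, and the grid
        reproduces the four rules."""
        for neck in np.linspace(0, 5, 41):
            for head in np.linspace(0, 1.2, 25):
                got = morph.classify_spine(neck, head)
                assert got in morph.SPINE_SUBTYPES
                if neck == 0:
                    assert got == "stubby"
                elif head >= 0.6:
                    assert got == "mushroom"
                elif neck > 3:
                    assert got == "filopodia"
                else:
                    assert got == "thin"

    def test_dead_zone_warns_thin(self):
        with pytest.warns(UserWarning, match="dead zone"):
            assert morph.classify_spine(3.0, 0.5) == "thin"

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            morph.classify_spine(-1.0, 0.5)


class TestSpineDensity:
    def test_ten_spines_on_100um(self):
        spines = [morph.SpineRecord(f"s{i}", 10.0 * i, 1.0, 0.3) for i in range(10)]
        seg = morph.DendriteSegment(100.0, 95.0, spines)
        assert morph.spine_density(seg)["total"] == pytest.approx(1.0)

    def test_empty_segment_zero(self):
        seg = morph.DendriteSegment(50.0)
        density = morph.spine_density(seg)
        assert all(v == 0.0 for v in density.values())

    def test_matches_counting_oracle(self, rng):
        for _ in range(20):
            length = float(rng.uniform(20, 120))
            n = int(rng.integers(0, 15))
            spines = [
                morph.SpineRecord(
                    f"s{i}", float(rng.uniform(0, length)),
                    float(rng.uniform(0, 4)), float(rng.uniform(0, 1)),
                )
                for i in range(n)
            ]
            seg = morph.DendriteSegment(length, 95.0, spines)
            density = morph.spine_density(seg)
            assert density["total"] == pytest.approx(n / length * 10.0)
            per_type = {t: sum(s.subtype == t for s in spines) for t in morph.SPINE_SUBTYPES}
            for t, c in per_type.items():
                assert density[t] == pytest.approx(c / length * 10.0)

    def test_zero_length_rejected(self):
        with pytest.raises(ValueError):
            morph.DendriteSegment(0.0)


class TestMinDistance:
    def test_pythagorean_345(self):
        cloud = morph.ProcessPointCloud([[3, 4, 0]], (0.04, 0.04, 0.3))
        d, zp = morph.min_distance_3d((0, 0, 0), cloud)
        assert d == pytest.approx(0.2)
        assert zp == 0

    def test_single_z_plane(self):
        cloud = morph.ProcessPointCloud([[0, 0, 1]], (0.04, 0.04, 0.3))
        d, zp = morph.min_distance_3d((0, 0, 0), cloud)
        assert d == pytest.approx(0.3)
        assert zp == 1

    def test_matches_brute_force_on_random_cloud(self, rng):
        voxel = (0.04, 0.04, 0.3)
        cloud = morph.ProcessPointCloud(rng.integers(-50, 50, size=(500, 3)), voxel)
        head = tuple(rng.integers(-50, 50, size=3))
        d, zp = morph.min_distance_3d(head, cloud)
        scaled = (cloud.voxels - np.array(head)) * np.array(voxel)
        dists = np.sqrt((scaled**2).sum(axis=1))
        assert d == pytest.approx(dists.min())
        assert d <= dists.max()

    def test_translation_invariance(self, rng):
        voxel = (0.04, 0.04, 0.3)
        pts = rng.integers(0, 30, size=(50, 3))
        shift = np.array([7, -3, 11])
        d1, z1 = morph.min_distance_3d((1, 2, 3), morph.ProcessPointCloud(pts, voxel))
        d2, z2 = morph.min_distance_3d(
            tuple(np.array([1, 2, 3]) + shift), morph.ProcessPointCloud(pts + shift, voxel)
        )
        assert d1 == pytest.approx(d2)
        assert z1 == z2

    def test_empty_cloud_rejected(self):
        cloud = morph.ProcessPointCloud(np.empty((0, 3)), (0.04, 0.04, 0.3))
        with pytest.raises(ValueError, match="empty"):
            morph.min_distance_3d((0, 0, 0), cloud)


class TestCoverage:
    def _ring_cloud(self, radius_um, n_points, voxel):
        angles = 2 * np.pi * np.arange(n_points) / n_points
        pts = np.stack(
            [
                np.rint(radius_um * np.cos(angles) / voxel[0]),
                np.rint(radius_um * np.sin(angles) / voxel[1]),
                np.zeros(n_points),
            ],
            axis=1,
        )
        return morph.ProcessPointCloud(pts.astype(int), voxel)

    def test_full_ring_is_one(self):
        voxel = (0.04, 0.04, 0.3)
        cloud = self._ring_cloud(0.3, 200, voxel)
        assert morph.coverage_fraction((0, 0, 0), 0.6, cloud) == 1.0

    def test_no_contact_is_zero(self):
        voxel = (0.04, 0.04, 0.3)
        cloud = morph.ProcessPointCloud([[100, 100, 0]], voxel)
        assert morph.coverage_fraction((0, 0, 0), 0.6, cloud) == 0.0

    def test_half_ring_is_half(self):
        """A half-annulus hugging the upper head perimeter covers the upper
        bins only; enumeration of covered bins gives 0.5 within one bin."""
        voxel = (0.01, 0.01, 0.3)
        ij = np.mgrid[-40:41, 0:41].reshape(2, -1).T
        r = np.sqrt((ij**2).sum(axis=1)) * 0.01
        ring = ij[(r >= 0.25) & (r <= 0.35)]
        cloud = morph.ProcessPointCloud(
            np.column_stack([ring, np.zeros(len(ring), dtype=int)]), voxel
        )
        frac = morph.coverage_fraction((0, 0, 0), 0.6, cloud, contact_radius_um=0.03)
        assert frac == pytest.approx(0.5, abs=1 / 36 + 1e-9)
        # oracle: angular enumeration of covered bins
        angles = 2 * np.pi * np.arange(36) / 36
        bins = 0.3 * np.column_stack([np.cos(angles), np.sin(angles)])
        pts = ring * 0.01
        d = np.sqrt(((bins[:, None, :] - pts[None, :, :]) ** 2).sum(axis=2)).min(axis=1)
        assert frac == pytest.approx((d <= 0.03).mean())


class TestClassifyInteraction:
    @pytest.mark.parametrize(
        "d,zp,cov,expected",
        [
            (0.2, 0, 0.6, "encapsulation"),
            (0.3, 1, 0.5, "encapsulation"),  # inclusive boundary
            (0.2, 0, 0.3, "apposition"),  # low coverage demotes
            (0.7, 2, 0.3, "apposition"),
            (0.9, 3, 0.0, "apposition"),
            (1.2, 4, 0.0, "proximity"),
            (1.5, 5, 0.0, "proximity"),
            (2.0, 0, 0.9, "none"),
            (0.2, 6, 0.9, "none"),  # distance fine but z-separation too large
        ],
    )
    def test_threshold_rules(self, d, zp, cov, expected):
        assert morph.classify_interaction(d, zp, cov) == expected

    def test_radii_consistent_with_z_planes(self):
        z_step = 0.3
        for cls, (radius, planes) in morph.INTERACTION_THRESHOLDS.items():
            assert radius == pytest.approx(planes * z_step)

    def test_monotone_in_distance(self):
        order = {c: i for i, c in enumerate(morph.INTERACTION_CLASSES)}
        for zp in (0, 1):
            for cov in (0.0, 0.6):
                classes = [
                    order[morph.classify_interaction(d, zp, cov)]
                    for d in np.linspace(0, 2.0, 41)
                ]
                assert classes == sorted(classes)


class TestInteractionDensity:
    def test_far_cloud_zero(self):
        spines = [morph.SpineRecord(f"s{i}", 10.0 * i, 1.0, 0.3) for i in range(5)]
        seg = morph.DendriteSegment(50.0, 95.0, spines)
        cloud = morph.ProcessPointCloud([[10_000, 10_000, 100]], (0.04, 0.04, 0.3))
        out = morph.interaction_density(seg, cloud)
        assert out["total"] == 0.0

    def test_constructed_scene_three_of_ten(self):
        voxel = (0.04, 0.04, 0.3)
        spines, clouds = [], {}
        for i in range(10):
            head = (int(10 * i / 0.04), 0, 0)
            spines.append(morph.SpineRecord(f"s{i}", 10.0 * i, 1.0, 0.3, head))
            # first 3 spines contacted (one z-plane away), rest far away
            offset = np.array([0, 0, 1]) if i < 3 else np.array([0, 2000, 50])
            clouds[f"s{i}"] = morph.ProcessPointCloud([np.array(head) + offset], voxel)
        seg = morph.DendriteSegment(100.0, 95.0, spines)
        out = morph.interaction_density(seg, clouds)
        assert out["total"] == pytest.approx(0.3)

    def test_class_counts_partition_total(self, rng):
        voxel = (0.04, 0.04, 0.3)
        spines, clouds = [], {}
        for i in range(12):
            head = (int(8 * i / 0.04), 0, 0)
            spines.append(
                morph.SpineRecord(
                    f"s{i}", 8.0 * i, float(rng.uniform(0, 4)), float(rng.uniform(0.1, 1)), head
                )
            )
            offset = rng.integers(0, 12, size=3)
            clouds[f"s{i}"] = morph.ProcessPointCloud([np.array(head) + offset], voxel)
        seg = morph.DendriteSegment(100.0, 95.0, spines)
        out = morph.interaction_density(seg, clouds)
        class_sum = sum(out[f"class:{c}"] for c in morph.INTERACTION_CLASSES[:-1])
        subtype_sum = sum(out[f"subtype:{t}"] for t in morph.SPINE_SUBTYPES)
        assert class_sum == pytest.approx(out["total"])
        assert subtype_sum == pytest.approx(out["total"])


class TestBranchOrder:
    def test_two_primaries_each_bifurcating(self):
        #        soma(1) -> 2 -> {3,4};  soma -> 5 -> {6,7}
        trace = _trace(
            [
                (1, 1, 0, 0, 0, -1),
                (2, 3, 1, 0, 0, 1),
                (3, 3, 2, 1, 0, 2),
                (4, 3, 2, -1, 0, 2),
                (5, 3, -1, 0, 0, 1),
                (6, 3, -2, 1, 0, 5),
                (7, 3, -2, -1, 0, 5),
            ]
        )
        assert morph.branch_order_counts(trace) == {1: 2, 2: 4}

    def test_single_unbranched_process(self):
        trace = _trace([(1, 1, 0, 0, 0, -1), (2, 3, 1, 0, 0, 1), (3, 3, 2, 0, 0, 2)])
        assert morph.branch_order_counts(trace) == {1: 1}

    def test_random_binary_trees_match_recursive_oracle(self, rng):
        for trial in range(10):
            rows = [(1, 1, 0.0, 0.0, 0.0, -1)]
            next_id = 2
            frontier = [1]
            for _ in range(int(rng.integers(3, 20))):
                parent = int(rng.choice(frontier))
                for _ in range(2):
                    rows.append(
                        (next_id, 3, float(rng.normal()), float(rng.normal()),
                         float(rng.normal()), parent)
                    )
                    frontier.append(next_id)
                    next_id += 1
            trace = _trace(rows)

            def oracle(trace):
                counts = {}

                def walk(node, order, fresh):
                    if fresh:
                        counts[order] = counts.get(order, 0) + 1
                    kids = trace.children[node]
                    if len(kids) == 1:
                        walk(kids[0], order, False)
                    else:
                        for k in kids:
                            walk(k, order + 1, True)

                for c in trace.children[trace.root]:
                    walk(c, 1, True)
                return counts

            assert morph.branch_order_counts(trace, max_order=100) == oracle(trace)

    def test_cycle_rejected(self):
        df = pd.DataFrame(
            [(1, 1, 0, 0, 0, -1), (2, 3, 1, 0, 0, 3), (3, 3, 2, 0, 0, 2)],
            columns=["node_id", "type", "x", "y", "z", "parent"],
        )
        df["radius"] = 0.5
        with pytest.raises(ValueError, match="cyclic"):
            morph.MicrogliaTrace(df)


class TestSholl:
    def test_straight_process_one_crossing_each(self):
        trace = _trace([(1, 1, 0, 0, 0, -1), (2, 3, 10, 0, 0, 1)])
        profile = morph.sholl(trace, range(1, 10))
        assert (profile.crossings == 1).all()

    def test_bifurcation_doubles_beyond_branch_point(self):
        trace = _trace(
            [
                (1, 1, 0, 0, 0, -1),
                (2, 3, 5, 0, 0, 1),
                (3, 3, 10, 3, 0, 2),
                (4, 3, 10, -3, 0, 2),
            ]
        )
        profile = morph.sholl(trace, [2.0, 4.0, 6.0, 8.0])
        assert list(profile.crossings[:2]) == [1, 1]
        assert list(profile.crossings[2:]) == [2, 2]

    def test_matches_dense_resampling_oracle(self, rng):
        rows = [(1, 1, 0.0, 0.0, 0.0, -1)]
        next_id = 2
        frontier = [(1, np.zeros(3))]
        for _ in range(15):
            parent, pos = frontier[int(rng.integers(len(frontier)))]
            new = pos + rng.normal(0, 3, 3)
            rows.append((next_id, 3, *new, parent))
            frontier.append((next_id, new))
            next_id += 1
        trace = _trace(rows)
        radii = np.arange(1.0, 12.0, 1.5)
        profile = morph.sholl(trace, radii)
        # oracle: resample every segment at 0.01 um and count sign changes
        for r, got in zip(radii, profile.crossings):
            crossings = 0
            for parent, kids in trace.children.items():
                p1 = trace.coords(parent) - trace.coords(trace.root)
                for k in kids:
                    p2 = trace.coords(k) - trace.coords(trace.root)
                    n = max(int(np.linalg.norm(p2 - p1) / 0.01), 2)
                    t = np.linspace(0, 1, n, endpoint=False)
                    d = np.linalg.norm(p1 + t[:, None] * (p2 - p1), axis=1) - r
                    crossings += int((np.diff(np.sign(d)) != 0).sum())
            assert got == crossings

    def test_pruned_subtree_never_exceeds_full(self, rng):
        rows = [(1, 1, 0.0, 0.0, 0.0, -1)]
        next_id = 2
        frontier = [(1, np.zeros(3))]
        for _ in range(20):
            parent, pos = frontier[int(rng.integers(len(frontier)))]
            new = pos + rng.normal(0, 2, 3)
            rows.append((next_id, 3, *new, parent))
            frontier.append((next_id, new))
            next_id += 1
        full = _trace(rows)
        kept = {1} | set(range(2, next_id - 5))
        pruned_rows = [r for r in rows if r[0] in kept and (r[5] == -1 or r[5] in kept)]
        pruned = _trace(pruned_rows)
        radii = np.arange(0.5, 8.0, 0.5)
        assert (morph.sholl(pruned, radii).crossings <= morph.sholl(full, radii).crossings).all()


class TestConvexHull:
    def test_unit_tetrahedron(self):
        trace = _trace(
            [
                (1, 1, 0, 0, 0, -1),
                (2, 3, 1, 0, 0, 1),
                (3, 3, 0, 1, 0, 1),
                (4, 3, 0, 0, 1, 1),
            ]
        )
        assert morph.convex_hull_volume(trace) == pytest.approx(1 / 6)

    def test_unit_cube(self):
        corners = list(itertools.product([0, 1], repeat=3))
        rows = [(1, 1, *corners[0], -1)] + [
            (i + 2, 3, *c, 1) for i, c in enumerate(corners[1:])
        ]
        assert morph.convex_hull_volume(_trace(rows)) == pytest.approx(1.0)

    def test_matches_delaunay_oracle(self, rng):
        from scipy.spatial import Delaunay

        pts = rng.normal(size=(30, 3)) * 5
        rows = [(1, 1, *pts[0], -1)] + [(i + 2, 3, *p, 1) for i, p in enumerate(pts[1:])]
        trace = _trace(rows)
        tri = Delaunay(pts)
        vol = 0.0
        for simplex in tri.simplices:
            a, b, c, d = pts[simplex]
            vol += abs(np.linalg.det(np.array([b - a, c - a, d - a]))) / 6.0
        assert morph.convex_hull_volume(trace) == pytest.approx(vol, rel=1e-9)

    def test_coplanar_warns_zero(self):
        rows = [(1, 1, 0, 0, 0, -1), (2, 3, 1, 0, 0, 1), (3, 3, 0, 1, 0, 1), (4, 3, 1, 1, 0, 1)]
        with pytest.warns(UserWarning, match="degenerate|fewer"):
            assert morph.convex_hull_volume(_trace(rows)) == 0.0


class TestPuncta:
    def test_five_puncta_fifty_um2(self):
        footprint = np.zeros((1, 2))
        puncta = np.zeros((5, 2))
        assert morph.puncta_interaction_density(puncta, footprint, 50.0) == pytest.approx(0.1)

    def test_no_puncta_zero(self):
        assert morph.puncta_interaction_density(np.empty((0, 2)), np.zeros((1, 2)), 10.0) == 0.0

    def test_matches_brute_force(self, rng):
        footprint = rng.uniform(0, 10, size=(40, 2))
        puncta = rng.uniform(0, 12, size=(60, 2))
        r, area = 0.5, 25.0
        got = morph.puncta_interaction_density(puncta, footprint, area, r)
        brute = sum(
            1 for p in puncta if min(np.linalg.norm(p - f) for f in footprint) <= r
        )
        assert got == pytest.approx(brute / area)

    def test_zero_area_rejected(self):
        with pytest.raises(ValueError):
            morph.puncta_interaction_density(np.zeros((1, 2)), np.zeros((1, 2)), 0.0)


class TestSwcIO:
    def test_round_trip(self, tmp_path):
        path = tmp_path / "cell.swc"
        path.write_text(
            "# synthetic microglia trace\n"
            "1 1 0.0 0.0 0.0 2.0 -1\n"
            "2 3 5.0 0.0 0.0 0.5 1\n"
            "3 3 8.0 2.0 0.5 0.4 2\n"
            "4 3 8.0 -2.0 -0.5 0.4 2\n"
        )
        trace = morph.read_swc(path)
        assert trace.root == 1
        assert morph.branch_order_counts(trace) == {1: 1, 2: 2}
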