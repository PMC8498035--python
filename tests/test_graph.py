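import numpy as np
import pytest

from canalpose.graph import (
    AmbiguityError,
    IdentificationError,
    Segment,
    TopologyError,
    crus_bifurcation,
    extract_segments,
    find_junctions,
    identify_canals,
    identify_key_points,
    identify_side,
    split_components,
    superior_hint,
)
from canalpose.io import CenterlineSet, Polyline
from canalpose.frame import HeadFrame


IDENTITY_AXES = HeadFrame(origin=np.zeros(3), x_axis=np.array([1.0, 0, 0]),
                          y_axis=np.array([0.0, 1, 0]), z_axis=np.array([0.0, 0, 1]))


def _cset(*polys):
    return CenterlineSet(subject_id="t", polylines=tuple(Polyline(np.asarray(p, float))
                                                         for p in polys))


class TestFindJunctions:
    def test_three_incidences_make_a_junction(self):
        shared = [5.0, 5.0, 5.0]
        cset = _cset([[0, 0, 0], shared], [[1, 0, 0], shared], [[0, 1, 0], shared])
        juncs = find_junctions(cset)
        assert len(juncs) == 1
        assert juncs[0].multiplicity == 3
        assert np.allclose(juncs[0].coordinate, shared)

    def test_two_incidences_do_not(self):
        shared = [5.0, 5.0, 5.0]
        cset = _cset([[0, 0, 0], shared], [[1, 0, 0], shared])
        assert find_junctions(cset) == []

    def test_weld_tolerance_groups_near_coincident_points(self):
        cset = _cset([[0, 0, 0], [5, 5, 5]], [[1, 0, 0], [5, 5, 5 + 1e-8]],
                     [[0, 1, 0], [5, 5 + 1e-8, 5]])
        assert len(find_junctions(cset, weld_tol=1e-6)) == 1
        assert len(find_junctions(cset, weld_tol=0.0)) == 0

    def test_synthetic_subject_matches_designed_junctions(self, clean_subject):
        juncs = find_junctions(clean_subject.centerlines)
        designed = clean_subject.truth.junctions
        assert len(juncs) == len(designed)
        got = np.array([j.coordinate for j in juncs])
        for d in designed:
            assert np.min(np.linalg.norm(got - d, axis=1)) < 1e-9


class TestExtractSegments:
    def test_interior_junction_splits_polyline(self):
        # three polylines meet at (1,0,0); the long one passes through it
        cset = _cset([[0, 0, 0], [1, 0, 0], [2, 0, 0]],
                     [[1, 1, 0], [1, 0, 0]], [[1, -1, 0], [1, 0, 0]])
        juncs = find_junctions(cset)
        segs = extract_segments(cset, juncs)
        assert len(segs) == 4  # split long polyline + two stubs
        lengths = sorted(s.arc_length for s in segs)
        assert np.allclose(lengths, [1, 1, 1, 1])

    def test_no_junction_keeps_polyline_whole(self):
        pts = np.outer(np.linspace(0, 10, 11), [1.0, 0, 0])
        segs = extract_segments(_cset(pts), [])
        assert len(segs) == 1
        assert segs[0].arc_length == pytest.approx(10.0, abs=1e-12)

    def test_split_lengths_sum_to_original(self, noisy_subject):
        cset = noisy_subject.centerlines
        juncs = find_junctions(cset)
        segs = extract_segments(cset, juncs)
        total = sum(s.arc_length for s in segs)
        orig = sum(p.length for p in cset.polylines)
        assert total == pytest.approx(orig, abs=1e-9)

    def test_synthetic_ring_lengths_match_truth(self, clean_subject):
        juncs = find_junctions(clean_subject.centerlines)
        segs = extract_segments(clean_subject.centerlines, juncs)
        expected = sorted(clean_subject.truth.ring_lengths.values(), reverse=True)
        got = sorted((s.arc_length for s in segs), reverse=True)[:6]
        # spline-free polygonal length slightly under the analytic arc length
        assert np.allclose(sorted(got), sorted(expected), rtol=0.01)


class TestIdentifyCanals:
    def _ring(self, midpoint, length, n=20):
        # a degenerate "ring": a half-circle-ish path with the given midpoint
        t = np.linspace(-0.5, 0.5, n)
        path = np.asarray(midpoint) + np.outer(t * length, [1.0, 0, 0])
        path[:, 1] += 0.01 * np.sin(np.pi * (t + 0.5))  # break collinearity
        return Segment(path=path, start_junction=None, end_junction=None)

    def test_position_rules_assign_labels(self):
        segs = [self._ring([0, -10, 0], 12.6),   # rearmost -> posterior
                self._ring([0, 0, 10], 11.7),    # uppermost -> superior
                self._ring([12, 0, 0], 10.0)]    # outermost -> lateral
        canals, warnings = identify_canals(segs, IDENTITY_AXES, side="right")
        assert canals["posterior"].segment_index == 0
        assert canals["superior"].segment_index == 1
        assert canals["lateral"].segment_index == 2
        assert warnings == []

    def test_length_order_violation_warns_but_keeps_position_labels(self):
        segs = [self._ring([0, -10, 0], 10.0),   # posterior but shortest
                self._ring([0, 0, 10], 11.7),
                self._ring([12, 0, 0], 12.6)]    # lateral but longest
        canals, warnings = identify_canals(segs, IDENTITY_AXES, side="right")
        assert canals["posterior"].segment_index == 0
        assert canals["lateral"].segment_index == 2
        assert len(warnings) == 1
        assert "ordering" in warnings[0]

    def test_ambiguous_positions_raise(self):
        segs = [self._ring([0, -10, 10], 12.6),  # rearmost AND uppermost
                self._ring([0, 0, 0], 11.7),
                self._ring([12, 0, 0], 10.0)]
        with pytest.raises(AmbiguityError):
            identify_canals(segs, IDENTITY_AXES, side="right")

    def test_too_few_candidates_raise(self):
        segs = [self._ring([0, -10, 0], 12.6), self._ring([0, 0, 10], 11.7)]
        with pytest.raises(IdentificationError, match=">= 3"):
            identify_canals(segs, IDENTITY_AXES, side="right")


class TestKeyPoints:
    def _side_anatomy(self, subject):
        cset = subject.centerlines
        juncs = find_junctions(cset)
        segs = extract_segments(cset, juncs)
        comps = split_components(segs)
        return segs, comps

    def test_key_points_recovered_exactly(self, clean_subject):
        segs, comps = self._side_anatomy(clean_subject)
        hint = superior_hint(segs, comps)
        assert hint @ [0, 0, 1] > 0.5  # identity pose: hint points superiorly
        for comp in comps:
            a = crus_bifurcation(segs, comp)
            side = "right" if a[0] < 0 else "left"
            anatomy = identify_side(segs, comp, IDENTITY_AXES, side)
            truth = clean_subject.truth.key_points[side]
            for k in "ABCDE":
                assert np.allclose(getattr(anatomy.key_points, k), truth[k], atol=1e-9)

    def test_b_equals_d_subject(self):
        from canalpose.synthetic import SubjectSpec, make_subject

        sub = make_subject(SubjectSpec.default(seed=31, noise_sd=0.0, b_equals_d=True))
        segs, comps = self._side_anatomy(sub)
        for comp in comps:
            a = crus_bifurcation(segs, comp)
            side = "right" if a[0] < 0 else "left"
            anatomy = identify_side(segs, comp, IDENTITY_AXES, side)
            assert np.array_equal(anatomy.key_points.B, anatomy.key_points.D)

    def test_polyline_order_and_direction_invariance(self, clean_subject):
        cset = clean_subject.centerlines
        rng = np.random.default_rng(8)
        perm = rng.permutation(len(cset.polylines))
        shuffled = CenterlineSet(
            subject_id="shuf",
            polylines=tuple(
                Polyline(cset.polylines[i].points[::-1] if i % 2 else cset.polylines[i].points)
                for i in perm))
        for source in (cset, shuffled):
            juncs = find_junctions(source)
            segs = extract_segments(source, juncs)
            comps = split_components(segs)
            kps = {}
            for comp in comps:
                a = crus_bifurcation(segs, comp)
                side = "right" if a[0] < 0 else "left"
                kps[side] = identify_side(segs, comp, IDENTITY_AXES, side).key_points
            if source is cset:
                reference = kps
        for side in ("left", "right"):
            for k in "ABCDE":
                assert np.allclose(getattr(kps[side], k), getattr(reference[side], k))

    def test_missing_shared_endpoint_raises(self):
        # posterior and superior arcs that do not touch
        def arc(center):
            t = np.linspace(0, 2, 20)
            p = np.asarray(center) + np.column_stack([t, np.sin(t), np.zeros_like(t)])
            return Segment(path=p, start_junction=None, end_junction=None)

        canals = {"posterior": None, "superior": None, "lateral": None}
        from canalpose.graph import LabeledCanal

        segs = [arc([0, 0, 0]), arc([10, 10, 10]), arc([5, 0, 5])]
        canals = {name: LabeledCanal(side="left", canal=name, arc=segs[i].path, segment_index=i)
                  for i, name in enumerate(["posterior", "superior", "lateral"])}
        with pytest.raises(TopologyError, match="common crus"):
            identify_key_points(canals, segs)


class TestComponents:
    def test_two_labyrinths_found(self, noisy_subject):
        cset = noisy_subject.centerlines
        juncs = find_junctions(cset)
        segs = extract_segments(cset, juncs)
        comps = split_components(segs)
        assert len(comps) == 2
        assert sorted(len(c) for c in comps) == [7, 7]
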