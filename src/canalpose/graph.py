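"""Centerline topology: junctions, segments, canal identities and key points.

The inner-ear centerline model is a bag of ordered polylines.  Coordinates
where at least three polyline points coincide (after welding within a small
tolerance) are junctions — the bifurcations where canal rings meet the common
crus and the utricle.  Polylines are split at junction incidences into
segments; per side, the three longest segments are the canal rings and are
labeled by the position of their midpoints:

* posterior canal — rearmost midpoint,
* superior (anterior) canal — uppermost midpoint,
* lateral (horizontal) canal — outermost (most lateral) midpoint,

with the cochlea–utricle line foremost.  Ring arc lengths are expected to
decrease posterior > superior > lateral; a violation downgrades to a warning
because the position rules take priority.  From the labeled arcs the key
points are read off: A is the superior shared endpoint of the posterior and
superior arcs (top of the common crus), D and C are their opposite endpoints,
B is the lateral arc endpoint nearest D (possibly coincident with it), and E
is the utricle point shared by the links leaving D and C.

Position words (rearmost/uppermost/outermost/foremost) need axes before the
standard frame exists, so identification accepts any axes object; a first
pass uses the image axes (MRI axes approximate the anatomical ones) and the
pipeline re-runs identification with the constructed head frame.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy.spatial import cKDTree

from .io import CenterlineSet

log = logging.getLogger(__name__)

__all__ = [
    "JunctionPoint",
    "Segment",
    "LabeledCanal",
    "KeyPointSet",
    "SideAnatomy",
    "IdentificationError",
    "AmbiguityError",
    "TopologyError",
    "find_junctions",
    "filter_junctions",
    "extract_segments",
    "split_components",
    "identify_canals",
    "identify_key_points",
    "identify_side",
    "crus_bifurcation",
    "superior_hint",
]

DEFAULT_WELD_TOL = 1e-6        # mm; guards against text-format rounding
DEFAULT_MIN_JUNCTION_SEP = 1.0  # mm; closer junction pairs are merged
DEFAULT_MIN_ARC = 2.0           # mm; junctions touching only shorter segments are dropped

CANALS = ("posterior", "superior", "lateral")


class IdentificationError(ValueError):
    """Raised when canal identification preconditions fail."""


class AmbiguityError(IdentificationError):
    """Raised when two segments claim the same canal label."""


class TopologyError(ValueError):
    """Raised when the centerline topology does not match the expected anatomy."""


@dataclass(frozen=True)
class JunctionPoint:
    """A welded coordinate with >= 3 polyline point incidences."""

    coordinate: np.ndarray
    multiplicity: int

    def __post_init__(self):
        object.__setattr__(self, "coordinate", np.asarray(self.coordinate, dtype=float))
        if self.multiplicity < 3:
            raise ValueError("junction multiplicity must be >= 3")


@dataclass(frozen=True)
class Segment:
    """A run of polyline points between junction incidences (or free ends)."""

    path: np.ndarray
    start_junction: int | None
    end_junction: int | None

    def __post_init__(self):
        object.__setattr__(self, "path", np.asarray(self.path, dtype=float))

    @property
    def arc_length(self) -> float:
        return float(np.linalg.norm(np.diff(self.path, axis=0), axis=1).sum())

    @property
    def midpoint(self) -> np.ndarray:
        """Point halfway along the polygonal path (by arc length)."""
        seg = np.linalg.norm(np.diff(self.path, axis=0), axis=1)
        s = np.concatenate([[0.0], np.cumsum(seg)])
        half = 0.5 * s[-1]
        i = int(np.searchsorted(s, half) - 1)
        i = max(0, min(i, len(seg) - 1))
        t = (half - s[i]) / seg[i] if seg[i] > 0 else 0.0
        return self.path[i] + t * (self.path[i + 1] - self.path[i])

    @property
    def endpoints(self) -> tuple[np.ndarray, np.ndarray]:
        return self.path[0], self.path[-1]


@dataclass(frozen=True)
class LabeledCanal:
    """One canal ring arc with its anatomical identity."""

    side: str
    canal: str
    arc: np.ndarray
    segment_index: int

    def __post_init__(self):
        object.__setattr__(self, "arc", np.asarray(self.arc, dtype=float))


@dataclass(frozen=True)
class KeyPointSet:
    """The landmark points of one labyrinth (B may coincide with D)."""

    A: np.ndarray
    B: np.ndarray
    C: np.ndarray
    D: np.ndarray
    E: np.ndarray

    def __post_init__(self):
        for name in "ABCDE":
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float))
        if np.allclose(self.A, self.C):
            raise TopologyError("key points A and C coincide")

    def as_dict(self) -> dict[str, np.ndarray]:
        return {k: getattr(self, k) for k in "ABCDE"}


@dataclass
class SideAnatomy:
    """Labeled canals, key points and warnings for one labyrinth."""

    side: str
    canals: dict[str, LabeledCanal]
    key_points: KeyPointSet
    cochlea_line: Segment | None
    warnings: list[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# junctions and segments

def _all_points(cset: CenterlineSet) -> tuple[np.ndarray, list[tuple[int, int]]]:
    pts, owners = [], []
    for pi, poly in enumerate(cset.polylines):
        for k, p in enumerate(poly.points):
            pts.append(p)
            owners.append((pi, k))
    return np.asarray(pts), owners


def _weld_clusters(pts: np.ndarray, tol: float) -> np.ndarray:
    """Union-find clustering of points within ``tol``; returns cluster labels."""
    parent = np.arange(len(pts))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    if tol > 0 and len(pts) > 1:
        pairs = cKDTree(pts).query_pairs(tol, output_type="ndarray")
        for a, b in pairs:
            ra, rb = find(a), find(b)
            if ra != rb:
                parent[max(ra, rb)] = min(ra, rb)
    else:
        # tol == 0: exact coordinate identity
        seen: dict[bytes, int] = {}
        for i, p in enumerate(pts):
            key = p.tobytes()
            if key in seen:
                parent[i] = seen[key]
            else:
                seen[key] = i
    return np.array([find(i) for i in range(len(pts))])


def find_junctions(cset: CenterlineSet, weld_tol: float = DEFAULT_WELD_TOL,
                   min_separation: float = DEFAULT_MIN_JUNCTION_SEP) -> list[JunctionPoint]:
    """Detect junction points: coordinates with >= 3 point incidences.

    Points within ``weld_tol`` are treated as one coordinate.  Junctions
    closer than ``min_separation`` to each other are merged (the inter-
    junction distances of a labyrinth follow a fixed anatomical pattern, and
    near-duplicate bifurcations are extraction artifacts).
    """
    if weld_tol < 0:
        raise ValueError("weld_tol must be >= 0")
    pts, _ = _all_points(cset)
    labels = _weld_clusters(pts, weld_tol)
    juncs = []
    for root in np.unique(labels):
        members = np.flatnonzero(labels == root)
        if len(members) >= 3:
            coord = pts[members].mean(axis=0)
            juncs.append((coord, len(members)))
    # merge junction pairs closer than min_separation
    if min_separation > 0 and len(juncs) > 1:
        coords = np.array([c for c, _ in juncs])
        merge = _weld_clusters(coords, min_separation)
        merged = []
        for root in np.unique(merge):
            members = np.flatnonzero(merge == root)
            if len(members) > 1:
                log.warning("merged %d junctions closer than %.3g mm", len(members), min_separation)
            mult = sum(juncs[i][1] for i in members)
            coord = np.average([juncs[i][0] for i in members], axis=0,
                               weights=[juncs[i][1] for i in members])
            merged.append((coord, mult))
        juncs = merged
    return [JunctionPoint(coordinate=c, multiplicity=m) for c, m in juncs]


def extract_segments(cset: CenterlineSet, junctions: list[JunctionPoint],
                     weld_tol: float = DEFAULT_WELD_TOL) -> list[Segment]:
    """Split every polyline at its junction incidences.

    A polyline point within ``weld_tol`` of a junction coordinate is an
    incidence; interior incidences cut the polyline.  Segment endpoints
    record the junction index (into ``junctions``) or ``None`` for free ends.
    """
    jcoords = np.array([j.coordinate for j in junctions]) if junctions else np.zeros((0, 3))
    tree = cKDTree(jcoords) if len(jcoords) else None
    segments: list[Segment] = []
    for poly in cset.polylines:
        pts = poly.points
        jidx = np.full(len(pts), -1)
        if tree is not None:
            dist, idx = tree.query(pts, distance_upper_bound=max(weld_tol, 1e-300))
            hit = np.isfinite(dist)
            jidx[hit] = idx[hit]
        cuts = [0] + [k for k in range(1, len(pts) - 1) if jidx[k] >= 0] + [len(pts) - 1]
        for a, b in zip(cuts[:-1], cuts[1:]):
            path = pts[a:b + 1]
            if len(path) < 2:
                continue
            sj = int(jidx[a]) if jidx[a] >= 0 else None
            ej = int(jidx[b]) if jidx[b] >= 0 else None
            segments.append(Segment(path=path, start_junction=sj, end_junction=ej))
    return segments


def split_components(segments: list[Segment], weld_tol: float = DEFAULT_WELD_TOL) -> list[list[int]]:
    """Group segments into connected components via shared endpoint coordinates.

    The two labyrinths are disjoint point sets, so a bilateral subject yields
    two components.  Returns lists of segment indices.
    """
    ends = np.array([p for s in segments for p in s.endpoints])
    labels = _weld_clusters(ends, weld_tol)
    g = nx.Graph()
    g.add_nodes_from(range(len(segments)))
    node_of_cluster: dict[int, int] = {}
    for si in range(len(segments)):
        for e in (2 * si, 2 * si + 1):
            cl = int(labels[e])
            if cl in node_of_cluster:
                g.add_edge(si, node_of_cluster[cl])
            else:
                node_of_cluster[cl] = si
    return [sorted(c) for c in nx.connected_components(g)]


def filter_junctions(cset: CenterlineSet, junctions: list[JunctionPoint],
                     min_arc: float = DEFAULT_MIN_ARC,
                     weld_tol: float = DEFAULT_WELD_TOL) -> list[JunctionPoint]:
    """Discard junctions that touch only segments shorter than ``min_arc``.

    Such junctions are extraction artifacts (spurious micro-bifurcations);
    the real bifurcations each carry at least one canal-scale arc.
    """
    segs = extract_segments(cset, junctions, weld_tol=weld_tol)
    keep = []
    for ji, j in enumerate(junctions):
        touching = [s for s in segs if ji in (s.start_junction, s.end_junction)]
        if touching and all(s.arc_length < min_arc for s in touching):
            log.warning("discarded junction at %s: only sub-%.3g mm segments attach",
                        np.round(j.coordinate, 3).tolist(), min_arc)
            continue
        keep.append(j)
    return keep


# ---------------------------------------------------------------------------
# identification

def _ring_candidates(segs: list[Segment], indices: list[int], min_arc: float) -> list[int]:
    """The three longest segments (above min_arc) are the canal rings."""
    usable = [i for i in indices if segs[i].arc_length > min_arc]
    if len(usable) < 3:
        raise IdentificationError(
            f"need >= 3 ring candidate segments, found {len(usable)} longer than {min_arc} mm")
    return sorted(usable, key=lambda i: segs[i].arc_length, reverse=True)[:3]


def identify_canals(segments: list[Segment], side_axes, side: str = "unknown",
                    indices: list[int] | None = None,
                    min_arc: float = DEFAULT_MIN_ARC) -> tuple[dict[str, LabeledCanal], list[str]]:
    """Label the canal rings of one labyrinth by midpoint position.

    ``side_axes`` supplies direction vectors: an object with attributes
    ``y_axis`` (anterior), ``z_axis`` (superior), ``x_axis`` (left) and
    ``origin`` — a :class:`~canalpose.frame.HeadFrame` or the provisional
    image-axes stand-in.  ``indices`` restricts to one side's segments.

    Returns the label->canal mapping and a list of warnings (raised to
    :class:`AmbiguityError` only when two rules pick the same segment).
    """
    if indices is None:
        indices = list(range(len(segments)))
    rings = _ring_candidates(segments, indices, min_arc)
    mids = np.array([segments[i].midpoint for i in rings])
    rel = mids - np.asarray(side_axes.origin, dtype=float)
    y = rel @ np.asarray(side_axes.y_axis, dtype=float)
    z = rel @ np.asarray(side_axes.z_axis, dtype=float)
    x = rel @ np.asarray(side_axes.x_axis, dtype=float)
    lateral = np.abs(x)

    pick = {
        "posterior": rings[int(np.argmin(y))],   # rearmost midpoint
        "superior": rings[int(np.argmax(z))],    # uppermost midpoint
        "lateral": rings[int(np.argmax(lateral))],  # outermost midpoint
    }
    if len(set(pick.values())) < 3:
        claimed: dict[int, list[str]] = {}
        for label, si in pick.items():
            claimed.setdefault(si, []).append(label)
        ties = {si: labs for si, labs in claimed.items() if len(labs) > 1}
        raise AmbiguityError(f"position rules are ambiguous: segments {ties} claim multiple labels")

    warnings: list[str] = []
    lp = segments[pick["posterior"]].arc_length
    ls = segments[pick["superior"]].arc_length
    ll = segments[pick["lateral"]].arc_length
    if not (lp > ls > ll):
        warnings.append(
            f"arc-length ordering violated: posterior {lp:.2f} mm, superior {ls:.2f} mm, "
            f"lateral {ll:.2f} mm (expected posterior > superior > lateral); labels kept by position")
    canals = {label: LabeledCanal(side=side, canal=label, arc=segments[si].path, segment_index=si)
              for label, si in pick.items()}
    return canals, warnings


def _shared_endpoint(a: Segment, b: Segment, weld_tol: float):
    """All endpoint coordinates shared between two segments (within weld_tol)."""
    shared = []
    for pa in a.endpoints:
        for pb in b.endpoints:
            if np.linalg.norm(pa - pb) <= weld_tol:
                shared.append(0.5 * (pa + pb))
    return shared


def _other_endpoint(seg: Segment, point: np.ndarray, weld_tol: float) -> np.ndarray:
    p0, p1 = seg.endpoints
    return p1 if np.linalg.norm(p0 - point) <= weld_tol else p0


def identify_key_points(canals: dict[str, LabeledCanal], segments: list[Segment],
                        side_axes=None, indices: list[int] | None = None,
                        weld_tol: float = DEFAULT_WELD_TOL) -> KeyPointSet:
    """Read the landmark points A–E off the labeled arcs and their links.

    A is the (more superior) endpoint shared by the posterior and superior
    arcs; D and C are those arcs' opposite endpoints; B is the lateral arc
    endpoint nearest D (equal to D when they coincide); E is the endpoint
    shared by the non-ring links leaving D and C toward the utricle.
    """
    for label in CANALS:
        if label not in canals:
            raise TopologyError(f"missing labeled canal {label!r}")
    post = segments[canals["posterior"].segment_index]
    sup = segments[canals["superior"].segment_index]
    lat = segments[canals["lateral"].segment_index]
    shared = _shared_endpoint(post, sup, weld_tol)
    if not shared:
        raise TopologyError("posterior and superior arcs share no endpoint (no common crus top)")
    if len(shared) > 1 and side_axes is not None:
        zax = np.asarray(side_axes.z_axis, dtype=float)
        shared.sort(key=lambda p: float(p @ zax), reverse=True)
    A = shared[0]
    D = _other_endpoint(post, A, weld_tol)
    C = _other_endpoint(sup, A, weld_tol)
    # B is the lateral arc's non-C endpoint (C is shared with the superior arc);
    # when both differ from C, fall back to the endpoint nearer D
    lat_ends = [p for p in lat.endpoints if np.linalg.norm(p - C) > weld_tol]
    if not lat_ends:
        raise TopologyError("lateral arc endpoints both coincide with C")
    B = min(lat_ends, key=lambda p: np.linalg.norm(p - D))
    if np.linalg.norm(B - D) <= weld_tol:
        B = D

    ring_idx = {c.segment_index for c in canals.values()}
    pool = indices if indices is not None else range(len(segments))
    links = [i for i in pool if i not in ring_idx]

    def link_other_end(anchor: np.ndarray):
        outs = []
        for i in links:
            seg = segments[i]
            for e in seg.endpoints:
                if np.linalg.norm(e - anchor) <= weld_tol:
                    outs.append(_other_endpoint(seg, anchor, weld_tol))
        return outs

    from_d = link_other_end(D)
    from_c = link_other_end(C)
    E = None
    for ed in from_d:
        for ec in from_c:
            if np.linalg.norm(ed - ec) <= weld_tol:
                E = 0.5 * (ed + ec)
                break
        if E is not None:
            break
    if E is None:
        # fall back: single link off D (or C) defines the utricle point
        if from_d:
            E = from_d[0]
        elif from_c:
            E = from_c[0]
        else:
            raise TopologyError("no utricle link found at D or C; cannot place key point E")
    return KeyPointSet(A=A, B=B, C=C, D=D, E=E)


def crus_bifurcation(segments: list[Segment], indices: list[int],
                     min_arc: float = DEFAULT_MIN_ARC,
                     weld_tol: float = DEFAULT_WELD_TOL) -> np.ndarray:
    """Locate the common-crus top (key point A) of one labyrinth, label-free.

    A is the endpoint shared by the two longest ring segments (posterior and
    superior canals) — a pose-invariant rule usable before any frame exists.
    """
    rings = _ring_candidates(segments, indices, min_arc)
    shared = _shared_endpoint(segments[rings[0]], segments[rings[1]], weld_tol)
    if not shared:
        raise TopologyError("two longest ring segments share no endpoint")
    return shared[0]


def superior_hint(segments: list[Segment], components: list[list[int]],
                  min_arc: float = DEFAULT_MIN_ARC,
                  weld_tol: float = DEFAULT_WELD_TOL) -> np.ndarray:
    """Anatomy-derived superior direction, usable before any frame exists.

    The common-crus bifurcation A is the *top* of the crus: the non-ring
    links leaving A run inferiorly into the vestibule.  Summing A minus the
    far endpoint of every link incident to A (over both labyrinths) gives a
    direction with a reliably positive superior component — pose-invariant,
    and built solely from junction coordinates, which are insensitive to
    centerline point noise.  Falls back to ring-midpoint geometry (the
    posterior ring hangs below the superior ring) if no link touches A.
    """
    acc = np.zeros(3)
    for comp in components:
        rings = _ring_candidates(segments, comp, min_arc)
        a_pt = None
        shared = _shared_endpoint(segments[rings[0]], segments[rings[1]], weld_tol)
        if shared:
            a_pt = shared[0]
        if a_pt is not None:
            ring_set = set(rings)
            for i in comp:
                if i in ring_set:
                    continue
                seg = segments[i]
                for e in seg.endpoints:
                    if np.linalg.norm(e - a_pt) <= weld_tol:
                        acc += a_pt - _other_endpoint(seg, a_pt, weld_tol)
    if np.linalg.norm(acc) <= 1e-9:
        for comp in components:
            rings = _ring_candidates(segments, comp, min_arc)
            acc += segments[rings[1]].midpoint - segments[rings[0]].midpoint
    n = np.linalg.norm(acc)
    if n <= 1e-9:
        raise IdentificationError("no usable superior direction from crus links or rings")
    return acc / n


def identify_side(segments: list[Segment], indices: list[int], side_axes, side: str,
                  min_arc: float = DEFAULT_MIN_ARC,
                  weld_tol: float = DEFAULT_WELD_TOL) -> SideAnatomy:
    """Full identification for one labyrinth: canal labels, key points, cochlea line."""
    canals, warnings = identify_canals(segments, side_axes, side=side,
                                       indices=indices, min_arc=min_arc)
    kps = identify_key_points(canals, segments, side_axes=side_axes,
                              indices=indices, weld_tol=weld_tol)
    ring_idx = {c.segment_index for c in canals.values()}
    others = [i for i in indices if i not in ring_idx]
    cochlea = None
    if others:
        yax = np.asarray(side_axes.y_axis, dtype=float)
        origin = np.asarray(side_axes.origin, dtype=float)
        cochlea_i = max(others, key=lambda i: float((segments[i].midpoint - origin) @ yax))
        cochlea = segments[cochlea_i]
    return SideAnatomy(side=side, canals=canals, key_points=kps,
                       cochlea_line=cochlea, warnings=warnings)
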