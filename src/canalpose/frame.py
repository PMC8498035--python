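"""Standard head coordinate frame from the crus bifurcations and the eyeball fundus.

The horizontal reference plane passes through the two common-crus bifurcation
points (one per labyrinth) and the lowest point of the eyeball.  "Lowest" is
defined self-consistently by a fixed-point iteration: start from the vertex
with minimum image z, form the plane through it and the two crus points, then
move to the eyeball vertex lying deepest on the inferior side of that plane,
and repeat until the selected vertex stops changing.

Axes of the resulting frame (convention ``"las"``):

* Z — the horizontal-plane normal, oriented superiorly (toward the eyeball
  bodies, which sit above their own lowest point),
* X — the unit vector from the right crus bifurcation to the left one,
  Gram-Schmidt-orthogonalized against Z,
* Y — ``Z x X``, pointing anteriorly,
* origin — midpoint of the two crus bifurcations.

Component signs are therefore x-positive-left, y-positive-anterior,
z-positive-superior.  A ``"ras"`` convention (x right, y anterior, z superior)
is also available.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

log = logging.getLogger(__name__)

__all__ = [
    "Plane",
    "HeadFrame",
    "FundusResult",
    "DegenerateGeometryError",
    "plane_from_points",
    "signed_distance",
    "fundus_point",
    "build_frame",
    "to_frame",
    "from_frame",
]


class DegenerateGeometryError(ValueError):
    """Raised when landmark geometry is too degenerate to define a plane or frame."""


def _unit(v: np.ndarray, what: str = "vector") -> np.ndarray:
    v = np.asarray(v, dtype=float)
    n = np.linalg.norm(v)
    if n <= 1e-300:
        raise DegenerateGeometryError(f"{what} has zero length")
    return v / n


@dataclass(frozen=True)
class Plane:
    """A plane given by a point on it and a unit normal."""

    point: np.ndarray
    normal: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "point", np.asarray(self.point, dtype=float))
        n = np.asarray(self.normal, dtype=float)
        if abs(np.linalg.norm(n) - 1.0) > 1e-12:
            raise DegenerateGeometryError("Plane normal must be unit length")
        object.__setattr__(self, "normal", n)


@dataclass(frozen=True)
class HeadFrame:
    """Origin plus three orthonormal axes defining the standard coordinate system."""

    origin: np.ndarray
    x_axis: np.ndarray
    y_axis: np.ndarray
    z_axis: np.ndarray
    convention_tag: str = "las"

    def __post_init__(self):
        o = np.asarray(self.origin, dtype=float)
        axes = [np.asarray(a, dtype=float) for a in (self.x_axis, self.y_axis, self.z_axis)]
        for a in axes:
            if abs(np.linalg.norm(a) - 1.0) > 1e-12:
                raise DegenerateGeometryError("frame axes must be unit vectors")
        for i in range(3):
            for j in range(i + 1, 3):
                if abs(float(axes[i] @ axes[j])) > 1e-10:
                    raise DegenerateGeometryError("frame axes must be orthogonal")
        object.__setattr__(self, "origin", o)
        object.__setattr__(self, "x_axis", axes[0])
        object.__setattr__(self, "y_axis", axes[1])
        object.__setattr__(self, "z_axis", axes[2])

    @property
    def rotation(self) -> np.ndarray:
        """3x3 matrix whose rows are the frame axes (world -> frame)."""
        return np.stack([self.x_axis, self.y_axis, self.z_axis])

    def to_dict(self) -> dict:
        return {
            "origin": self.origin.tolist(),
            "x_axis": self.x_axis.tolist(),
            "y_axis": self.y_axis.tolist(),
            "z_axis": self.z_axis.tolist(),
            "convention_tag": self.convention_tag,
        }


def plane_from_points(p1, p2, p3) -> Plane:
    """Plane through three non-collinear points.

    Normal sign convention: positive third component; ties broken by positive
    second, then first component.
    """
    p1, p2, p3 = (np.asarray(p, dtype=float) for p in (p1, p2, p3))
    n = np.cross(p2 - p1, p3 - p1)
    area = 0.5 * np.linalg.norm(n)
    if area <= 1e-9:
        raise DegenerateGeometryError(f"points are (near-)collinear: triangle area {area:.3g} mm^2")
    n = n / np.linalg.norm(n)
    for k in (2, 1, 0):
        if abs(n[k]) > 1e-12:
            if n[k] < 0:
                n = -n
            break
    return Plane(point=p1, normal=n)


def signed_distance(plane: Plane, q) -> float:
    """Signed distance (mm) from q to the plane; positive on the normal side."""
    q = np.asarray(q, dtype=float)
    return float(plane.normal @ (q - plane.point))


@dataclass(frozen=True)
class FundusResult:
    """Outcome of the lowest-eyeball-point fixed-point iteration."""

    point: np.ndarray
    plane: Plane
    iterations: int
    vertex_index: int
    converged: bool
    side: str | None = None


def fundus_point(eyeballs, crus_left, crus_right, max_iter: int = 100,
                 superior_hint=None) -> FundusResult:
    """Find the lowest eyeball point defining the horizontal plane.

    Vertices of all supplied eyeball surfaces are pooled.  Starting from the
    vertex with minimum coordinate along ``superior_hint``, iterate: form the
    plane through the current vertex and both crus bifurcations, orient its
    normal along the hint (superior), then select the vertex with the most
    negative signed distance (deepest inferior).  Stops when no vertex lies
    strictly deeper than the current one; on a cycle, keeps the deepest
    vertex seen and warns.

    ``superior_hint`` defaults to the image +z axis (head scanned upright in
    the image frame).  A tangent plane exists on either side of the crus
    line, so the hint decides which of the two fixed points is the anatomical
    fundus plane; callers with posed data should supply an anatomy-derived
    hint (see :func:`canalpose.graph.superior_hint`).
    """
    surfs = list(eyeballs)
    if not surfs:
        raise DegenerateGeometryError("no eyeball surfaces supplied")
    crus_left = np.asarray(crus_left, dtype=float)
    crus_right = np.asarray(crus_right, dtype=float)
    if np.linalg.norm(crus_left - crus_right) <= 1e-9:
        raise DegenerateGeometryError("crus bifurcation points coincide")
    hint = _unit(np.array([0.0, 0.0, 1.0]) if superior_hint is None
                 else np.asarray(superior_hint, dtype=float), "superior_hint")
    pools, sides = [], []
    for s in surfs:
        pools.append(s.points)
        sides.extend([s.side] * len(s.points))
    pts = np.vstack(pools)

    def oriented_plane(vertex):
        plane = plane_from_points(crus_left, crus_right, vertex)
        if float(plane.normal @ hint) < 0:
            plane = Plane(plane.point, -plane.normal)
        return plane

    idx = int(np.argmin(pts @ hint))
    best_idx, best_depth = idx, -np.inf
    seen: dict[int, int] = {}
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        plane = oriented_plane(pts[idx])
        d = pts @ plane.normal - plane.point @ plane.normal
        # no vertex strictly deeper than the current one => fixed point
        # (ties within 1e-9 mm absorb symmetric two-eye tangency)
        if d.min() >= float(d[idx]) - 1e-9:
            converged = True
            break
        nxt = int(np.argmin(d))
        depth = -float(d[nxt])
        if depth > best_depth:
            best_depth, best_idx = depth, nxt
        if nxt in seen:  # cycle on the discrete mesh
            log.warning("fundus iteration cycled after %d steps; keeping deepest vertex", it)
            break
        seen[idx] = it
        idx = nxt
    if not converged and it >= max_iter:
        log.warning("fundus iteration did not converge in %d steps", max_iter)
    if not converged:
        idx = best_idx
    # canonical tie-break: among vertices tangent at the final depth, keep the
    # lowest pooled index (stable under rigid motion of the whole subject)
    plane = oriented_plane(pts[idx])
    d = pts @ plane.normal - plane.point @ plane.normal
    ties = np.flatnonzero(d <= d[idx] + 1e-9)
    if len(ties) and int(ties.min()) != idx:
        idx = int(ties.min())
        plane = oriented_plane(pts[idx])
    side = sides[idx]
    log.info("fundus point from %s eyeball after %d iterations", side, it)
    return FundusResult(point=pts[idx].copy(), plane=plane, iterations=it,
                        vertex_index=idx, converged=converged, side=side)


def build_frame(crus_left, crus_right, fundus_plane: Plane,
                convention_tag: str = "las") -> HeadFrame:
    """Assemble the standard head frame.

    ``fundus_plane.normal`` must already be oriented superiorly (as returned
    by :func:`fundus_point`).  The origin is the crus midpoint.
    """
    crus_left = np.asarray(crus_left, dtype=float)
    crus_right = np.asarray(crus_right, dtype=float)
    sep = np.linalg.norm(crus_left - crus_right)
    if sep <= 1.0:
        raise DegenerateGeometryError(f"crus separation {sep:.3g} mm too small (need > 1 mm)")
    z = np.asarray(fundus_plane.normal, dtype=float)
    x_raw = crus_left - crus_right
    x_proj = x_raw - (x_raw @ z) * z
    if np.linalg.norm(x_proj) <= 1e-9 * sep:
        raise DegenerateGeometryError("crus line is parallel to the horizontal-plane normal")
    x = _unit(x_proj, "X axis")
    y = np.cross(z, x)  # anterior when x is leftward and z superior
    origin = 0.5 * (crus_left + crus_right)
    if convention_tag == "las":
        return HeadFrame(origin, x, y, z, "las")
    if convention_tag == "ras":
        return HeadFrame(origin, -x, y, z, "ras")
    raise ValueError(f"unknown convention_tag {convention_tag!r}")


def to_frame(coords, frame: HeadFrame, is_direction: bool = False) -> np.ndarray:
    """Express world points (or free direction vectors) in frame coordinates."""
    coords = np.asarray(coords, dtype=float)
    r = frame.rotation
    if is_direction:
        return coords @ r.T
    return (coords - frame.origin) @ r.T


def from_frame(coords, frame: HeadFrame, is_direction: bool = False) -> np.ndarray:
    """Inverse of :func:`to_frame`."""
    coords = np.asarray(coords, dtype=float)
    r = frame.rotation
    if is_direction:
        return coords @ r
    return coords @ r + frame.origin
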