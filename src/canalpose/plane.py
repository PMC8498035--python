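"""Canal-plane fitting: spline resampling, orthogonal least squares, direction angles.

A canal's centerline arc is unevenly sampled (dense on curvature, sparse on
straights), which would bias a plane fit toward the dense stretches.  The arc
is therefore first interpolated with a chord-length-parameterized cubic spline
and resampled at uniform arc-length steps; the plane is then fit by orthogonal
(total) least squares — the normal is the smallest principal direction of the
centered point covariance, which is well behaved even for near-vertical canal
planes where a functional fit z = f(x, y) would fail.

The attitude of the plane is reported as the unit normal in the standard head
frame together with its three direction angles: the angle between the canal
plane and the sagittal / coronal / horizontal coordinate plane equals the
angle between their normals, i.e. arccos of the corresponding normal
component.  Angles are kept in [0°, 180°] (no folding to acute angles).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.interpolate import make_interp_spline

from .frame import Plane

log = logging.getLogger(__name__)

__all__ = [
    "ResampledArc",
    "CanalAttitude",
    "spline_resample",
    "fit_plane_tls",
    "orient_normal",
    "direction_angles",
    "canal_attitude",
]

#: default number of uniformly spaced points fed to the plane fit
DEFAULT_N_OUT = 200


@dataclass(frozen=True)
class ResampledArc:
    """Arc points resampled at (approximately) uniform arc-length spacing."""

    points: np.ndarray

    def __post_init__(self):
        pts = np.asarray(self.points, dtype=float)
        if len(pts) < 10:
            raise ValueError(f"ResampledArc needs >= 10 points, got {len(pts)}")
        object.__setattr__(self, "points", pts)


@dataclass(frozen=True)
class CanalAttitude:
    """A canal plane's orientation in the standard head frame.

    ``direction_angles`` are (sagittal, coronal, horizontal) in degrees;
    their cosines are the components of ``unit_normal``.
    """

    side: str
    canal: str
    unit_normal: np.ndarray
    direction_angles: tuple[float, float, float]
    fit_rms: float

    def to_dict(self) -> dict:
        return {
            "side": self.side,
            "canal": self.canal,
            "unit_normal": np.asarray(self.unit_normal).tolist(),
            "direction_angles_deg": list(self.direction_angles),
            "fit_rms_mm": self.fit_rms,
        }


def spline_resample(arc, n_out: int = DEFAULT_N_OUT) -> ResampledArc:
    """Resample an ordered 3D arc at uniform arc-length steps.

    An interpolating cubic spline with chord-length parameterization passes
    through every input point; the spline is then evaluated at parameter
    values corresponding to equal increments of arc length.  Endpoints are
    returned exactly.  Coincident consecutive input points are dropped with a
    warning.
    """
    pts = np.asarray(arc, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3:
        raise ValueError("arc must be an (N, 3) array")
    keep = np.ones(len(pts), dtype=bool)
    keep[1:] = np.linalg.norm(np.diff(pts, axis=0), axis=1) > 0
    if not keep.all():
        log.warning("spline_resample: dropped %d coincident consecutive points", int((~keep).sum()))
        pts = pts[keep]
    if len(pts) < 4:
        raise ValueError(f"need >= 4 distinct points for cubic spline, got {len(pts)}")
    if n_out < 10:
        raise ValueError("n_out must be >= 10")

    chord = np.concatenate([[0.0], np.cumsum(np.linalg.norm(np.diff(pts, axis=0), axis=1))])
    spline = make_interp_spline(chord, pts, k=3)

    # arc-length reparameterization on a dense dyadic refinement of the knots
    dense_t = np.linspace(chord[0], chord[-1], max(20 * n_out, 1000))
    dense_p = spline(dense_t)
    seg = np.linalg.norm(np.diff(dense_p, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    targets = np.linspace(0.0, s[-1], n_out)
    t_of_s = np.interp(targets, s, dense_t)
    out = spline(t_of_s)
    out[0], out[-1] = pts[0], pts[-1]  # exact endpoints
    return ResampledArc(points=out)


def fit_plane_tls(points) -> tuple[Plane, float]:
    """Orthogonal least-squares plane fit.

    Returns the plane through the centroid whose normal (smallest principal
    direction of the centered covariance) minimizes the sum of squared
    perpendicular distances, plus the RMS perpendicular residual (mm).
    """
    pts = np.asarray(getattr(points, "points", points), dtype=float)
    if len(pts) < 3:
        raise ValueError(f"need >= 3 points to fit a plane, got {len(pts)}")
    centroid = pts.mean(axis=0)
    centered = pts - centroid
    _, s, vt = np.linalg.svd(centered, full_matrices=False)
    if s[0] <= 1e-300 or (s[1] - s[2]) <= 1e-12 * s[0]:
        raise ValueError("degenerate point set: plane normal is not uniquely defined")
    normal = vt[2]
    rms = float(s[2] / np.sqrt(len(pts)))
    return Plane(point=centroid, normal=normal), rms


def orient_normal(normal) -> np.ndarray:
    """Resolve the sign ambiguity of a plane normal.

    Flips the vector so its superior (third) component is positive; if that
    component vanishes, requires the anterior (second), then the left (first)
    component to be positive.
    """
    n = np.asarray(normal, dtype=float).copy()
    for k in (2, 1, 0):
        if abs(n[k]) >= 1e-9:
            return -n if n[k] < 0 else n
    return n


def direction_angles(unit_normal, unit_tol: float = 1e-3) -> tuple[float, float, float]:
    """Direction angles (degrees) of a unit normal: arccos of its components.

    These equal the angles between the canal plane and the sagittal, coronal
    and horizontal coordinate planes respectively.  The components are used
    as given (no renormalization), so a vector quoted to a few decimals
    reproduces the angles computed from those printed components; the norm
    must still be within ``unit_tol`` of 1.
    """
    v = np.asarray(unit_normal, dtype=float)
    if abs(np.linalg.norm(v) - 1.0) > unit_tol:
        raise ValueError(f"expected a unit vector (|v| within {unit_tol} of 1), got |v|={np.linalg.norm(v):.6f}")
    ang = np.degrees(np.arccos(np.clip(v, -1.0, 1.0)))
    return (float(ang[0]), float(ang[1]), float(ang[2]))


def canal_attitude(side: str, canal: str, arc_in_frame, n_out: int = DEFAULT_N_OUT) -> CanalAttitude:
    """Fit one canal's plane from its arc (already in head-frame coordinates)."""
    resampled = spline_resample(arc_in_frame, n_out=n_out)
    plane, rms = fit_plane_tls(resampled)
    n = orient_normal(plane.normal)
    return CanalAttitude(side=side, canal=canal, unit_normal=n,
                         direction_angles=direction_angles(n, unit_tol=1e-9), fit_rms=rms)
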