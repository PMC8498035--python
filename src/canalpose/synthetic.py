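"""Synthetic labyrinth generator with known ground-truth canal orientations.

Builds per-subject inner-ear centerline models with the canonical topology of
the bilateral labyrinth — per side: a posterior canal ring arc A–D, a superior
canal ring arc A–C, a lateral canal ring arc B–C, the common-crus line A–E,
utricle links D–E and C–E, and a cochlea–utricle line leaving E — together
with icosphere eyeball meshes, so the whole measurement pipeline can be
exercised without any imaging data.

Construction is done in "standard" anatomical coordinates (x positive left,
y anterior, z superior): the crus bifurcations A sit at (±30, 0, 0) mm and
the eyeball centers at (±31, 70, 12) mm with radius 12 mm, so the lowest
eyeball points are level with the crus bifurcations and the ground-truth
horizontal plane is z = 0.  An arbitrary rigid pose (the scanner placement of
the head) is then applied to everything.

Canal ring sizes default to radius 3.0 / 2.8 / 2.4 mm with a 240° arc span
for the posterior / superior / lateral canal, giving arc lengths 12.6 > 11.7
> 10.0 mm, so the anatomical length ordering holds.  Point spacing along the
arcs is deliberately non-uniform (denser in some stretches) to emulate
centerline-extraction output, and isotropic Gaussian point noise is added to
interior points only — arc endpoints are noise-free so junction coordinates
are bit-identical across the polylines that meet there.

Cohorts draw each subject's six canal normals independently from von
Mises–Fisher distributions around population mean orientations; the default
population means are the published standard normal vectors for the adult
posterior / superior / lateral canals of each side, and the default
concentrations are calibrated so that the mean angular deviation from the
population mean matches the reported inter-subject dispersion (≈5–7°).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import quad
from scipy.optimize import brentq

from .io import CenterlineSet, EyeballSurface, Polyline

__all__ = [
    "CanalSpec",
    "SubjectSpec",
    "CohortSpec",
    "GroundTruth",
    "SyntheticSubject",
    "REFERENCE_NORMALS",
    "REFERENCE_DEVIATION_DEG",
    "make_canal_arc",
    "make_subject",
    "make_cohort",
    "sample_vmf",
    "vmf_mean_deviation_deg",
    "kappa_for_mean_deviation",
    "random_rigid_pose",
]

SIDES = ("right", "left")
CANALS = ("posterior", "superior", "lateral")

#: published standard (population mean) unit normals of the six canal planes
#: in the standard head frame (x left, y anterior, z superior), right/left ×
#: posterior/superior/lateral.
REFERENCE_NORMALS: dict[tuple[str, str], tuple[float, float, float]] = {
    ("right", "posterior"): (-0.651, 0.702, 0.287),
    ("right", "superior"): (0.749, 0.577, 0.324),
    ("right", "lateral"): (-0.017, -0.299, 0.954),
    ("left", "posterior"): (0.660, 0.702, 0.266),
    ("left", "superior"): (-0.739, 0.588, 0.329),
    ("left", "lateral"): (0.025, -0.279, 0.960),
}

#: reported mean angular deviation (degrees) of individual canal normals from
#: the population mean; used to calibrate the default vMF concentrations.
REFERENCE_DEVIATION_DEG: dict[tuple[str, str], float] = {
    ("right", "posterior"): 5.26,
    ("right", "superior"): 5.31,
    ("right", "lateral"): 6.94,
    ("left", "posterior"): 5.40,
    ("left", "superior"): 5.60,
    ("left", "lateral"): 6.73,
}

_RADII = {"posterior": 3.0, "superior": 2.8, "lateral": 2.4}
_ARC_SPAN = 240.0
_EYE_RADIUS = 12.0
_EYE_SUBDIV = 4

_Z = np.array([0.0, 0.0, 1.0])
_Y = np.array([0.0, 1.0, 0.0])
_X = np.array([1.0, 0.0, 0.0])


def _unit(v):
    v = np.asarray(v, dtype=float)
    n = np.linalg.norm(v)
    if n == 0:
        raise ValueError("zero vector")
    return v / n


def _project_unit(v, normal):
    """Unit projection of v onto the plane with the given unit normal."""
    v = np.asarray(v, dtype=float)
    p = v - (v @ normal) * normal
    n = np.linalg.norm(p)
    return p / n if n > 1e-9 else None


def _rotate_about(v, axis, angle_deg):
    """Rotate an in-plane unit vector about the plane normal (Rodrigues)."""
    a = math.radians(angle_deg)
    return math.cos(a) * v + math.sin(a) * np.cross(axis, v)


@dataclass(frozen=True)
class CanalSpec:
    """One canal ring arc: a circular arc in the plane with the given normal."""

    true_normal: np.ndarray
    center: np.ndarray
    radius: float
    arc_span: float = _ARC_SPAN
    n_points: int = 60
    noise_sd: float = 0.0
    start_direction: np.ndarray | None = None  # in-plane unit vector to the first point
    sweep: int = 1  # +1 / -1 rotation sense about true_normal
    spacing_warp: float = 0.1  # non-uniformity of point spacing along the arc

    def __post_init__(self):
        n = np.asarray(self.true_normal, dtype=float)
        if abs(np.linalg.norm(n) - 1.0) > 1e-12:
            raise ValueError("true_normal must be a unit vector (within 1e-12)")
        object.__setattr__(self, "true_normal", n)
        object.__setattr__(self, "center", np.asarray(self.center, dtype=float))
        if self.radius <= 0:
            raise ValueError("radius must be positive")
        if not (0.0 < self.arc_span <= 360.0):
            raise ValueError("arc_span must be in (0, 360] degrees")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


def make_canal_arc(spec: CanalSpec, rng: np.random.Generator | None = None) -> np.ndarray:
    """Sample an ordered arc of points on the canal circle.

    Points lie exactly in the plane through ``spec.center`` with normal
    ``spec.true_normal``; spacing along the arc is mildly non-uniform.  When
    ``spec.noise_sd`` > 0 the interior points get isotropic Gaussian noise
    (endpoints stay exact so junctions weld bit-identically).
    """
    if spec.n_points < 3:
        raise ValueError("n_points must be >= 3")
    n = spec.true_normal
    u = spec.start_direction
    if u is None:
        for cand in (-_Z, -_Y, -_X):
            u = _project_unit(cand, n)
            if u is not None:
                break
    else:
        u = _unit(np.asarray(u, dtype=float) - (np.asarray(u, dtype=float) @ n) * n)
    v = np.cross(n, u)
    frac = np.linspace(0.0, 1.0, spec.n_points)
    if spec.spacing_warp:
        frac = frac + spec.spacing_warp * np.sin(2 * np.pi * frac) / (2 * np.pi)
    theta = np.radians(spec.arc_span) * frac * spec.sweep
    pts = (spec.center[None, :]
           + spec.radius * np.cos(theta)[:, None] * u[None, :]
           + spec.radius * np.sin(theta)[:, None] * v[None, :])
    if spec.noise_sd > 0:
        if rng is None:
            raise ValueError("noise_sd > 0 requires an rng")
        noise = rng.normal(scale=spec.noise_sd, size=pts.shape)
        noise[0] = 0.0
        noise[-1] = 0.0
        pts = pts + noise
    return pts


# ---------------------------------------------------------------------------
# von Mises–Fisher machinery

def sample_vmf(mean_direction, kappa: float, n: int, rng: np.random.Generator) -> np.ndarray:
    """Draw ``n`` unit vectors from a von Mises–Fisher distribution on S².

    Uses the inversion formula for the cosine of the polar angle and a
    Householder reflection to rotate the pole onto the mean direction.
    """
    if kappa <= 0:
        raise ValueError("kappa must be > 0")
    mu = _unit(mean_direction)
    u = rng.random(n)
    # w = cos(theta); inversion of the vMF marginal, stable for large kappa
    w = 1.0 + np.log(u + (1.0 - u) * np.exp(-2.0 * kappa)) / kappa
    w = np.clip(w, -1.0, 1.0)
    phi = rng.uniform(0.0, 2.0 * np.pi, n)
    r = np.sqrt(np.maximum(0.0, 1.0 - w ** 2))
    samples = np.column_stack([r * np.cos(phi), r * np.sin(phi), w])
    # Householder reflection mapping e_z to mu
    e_z = np.array([0.0, 0.0, 1.0])
    if np.allclose(mu, e_z, atol=1e-15):
        return samples
    x = _unit(e_z - mu)
    return samples - 2.0 * (samples @ x)[:, None] * x[None, :]


def vmf_mean_deviation_deg(kappa: float) -> float:
    """Expected angle (degrees) between a vMF draw and its mean direction."""
    if kappa <= 0:
        raise ValueError("kappa must be > 0")
    upper = min(2.0 * kappa, 60.0)

    def integrand(s):
        return math.acos(max(-1.0, 1.0 - s / kappa)) * math.exp(-s)

    num, _ = quad(integrand, 0.0, upper, limit=200)
    den = 1.0 - math.exp(-2.0 * kappa) if kappa < 350 else 1.0
    return math.degrees(num / den)


def kappa_for_mean_deviation(target_deg: float) -> float:
    """Concentration κ whose expected angular deviation equals ``target_deg``."""
    if not (0 < target_deg < 90):
        raise ValueError("target mean deviation must be in (0, 90) degrees")
    lo, hi = 1e-2, 1e9
    f = lambda logk: vmf_mean_deviation_deg(10.0 ** logk) - target_deg
    return 10.0 ** brentq(f, math.log10(lo), math.log10(hi), xtol=1e-10)


def random_rigid_pose(rng: np.random.Generator,
                      translation_scale: float = 25.0) -> tuple[np.ndarray, np.ndarray]:
    """A uniformly random rotation and a random translation (mm)."""
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    rot = np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
        [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
        [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
    ])
    t = rng.uniform(-translation_scale, translation_scale, size=3)
    return rot, t


# ---------------------------------------------------------------------------
# subjects

@dataclass(frozen=True)
class GroundTruth:
    """Everything the generator knows: true normals, landmarks, pose, topology."""

    normals: dict[tuple[str, str], np.ndarray]
    key_points: dict[str, dict[str, np.ndarray]]
    junctions: list[np.ndarray]
    ring_lengths: dict[tuple[str, str], float]
    rotation: np.ndarray
    translation: np.ndarray


@dataclass(frozen=True)
class SyntheticSubject:
    subject_id: str
    centerlines: CenterlineSet
    eyeballs: dict[str, EyeballSurface]
    truth: GroundTruth


@dataclass(frozen=True)
class SubjectSpec:
    """Full recipe for one synthetic subject (pre-pose, standard coordinates)."""

    subject_id: str
    normals: dict[tuple[str, str], np.ndarray]
    crus_points: dict[str, np.ndarray]
    eyeball_centers: dict[str, np.ndarray]
    eyeball_radius: float
    noise_sd: float
    rotation: np.ndarray
    translation: np.ndarray
    seed: int
    b_equals_d: bool = False
    n_arc_points: int = 60

    @staticmethod
    def default(seed: int, subject_id: str = "synthetic-000",
                normals: dict[tuple[str, str], np.ndarray] | None = None,
                noise_sd: float = 0.05,
                pose: tuple[np.ndarray, np.ndarray] | None = None,
                b_equals_d: bool = False) -> "SubjectSpec":
        if normals is None:
            normals = {k: _unit(v) for k, v in REFERENCE_NORMALS.items()}
        else:
            normals = {k: _unit(v) for k, v in normals.items()}
        if pose is None:
            rot, t = np.eye(3), np.zeros(3)
        else:
            rot, t = pose
        return SubjectSpec(
            subject_id=subject_id,
            normals=normals,
            crus_points={"right": np.array([-30.0, 0.0, 0.0]),
                         "left": np.array([30.0, 0.0, 0.0])},
            eyeball_centers={"right": np.array([-31.0, 70.0, _EYE_RADIUS]),
                             "left": np.array([31.0, 70.0, _EYE_RADIUS])},
            eyeball_radius=_EYE_RADIUS,
            noise_sd=noise_sd,
            rotation=np.asarray(rot, dtype=float),
            translation=np.asarray(t, dtype=float),
            seed=int(seed),
            b_equals_d=b_equals_d,
        )


def _arc_endpoint_choice(center, radius, normal, start, span_deg, prefer):
    """Return the sweep sign whose arc endpoint maximizes ``prefer`` (a score fn)."""
    u = _unit(start - center)
    v = np.cross(normal, u)
    th = math.radians(span_deg)
    ends = {}
    for sweep in (1, -1):
        ends[sweep] = center + radius * (math.cos(th * sweep) * u + math.sin(th * sweep) * v)
    return max(ends, key=lambda s: prefer(ends[s])), ends


def _line_points(p0, p1, n_pts, noise_sd, rng):
    """Straight polyline from p0 to p1 with noisy interior, exact endpoints."""
    frac = np.linspace(0.0, 1.0, n_pts)
    pts = p0[None, :] + frac[:, None] * (p1 - p0)[None, :]
    if noise_sd > 0:
        noise = rng.normal(scale=noise_sd, size=pts.shape)
        noise[0] = 0.0
        noise[-1] = 0.0
        pts = pts + noise
    return pts


def _ring_through_two_points(p, q, normal_pref, radius_min, bulge_pref):
    """Circular arc through two fixed points, in the plane closest to ``normal_pref``.

    The plane is forced to contain the chord p–q (smallest rotation of
    ``normal_pref``); the radius grows beyond ``radius_min`` if the chord
    demands it; of the two candidate centers the one maximizing
    ``bulge_pref(arc midpoint)`` is taken.  Returns a CanalSpec-style tuple
    (center, normal, radius, start direction at p, span_deg, sweep) for the
    long arc p → q.
    """
    p = np.asarray(p, float)
    q = np.asarray(q, float)
    chord = q - p
    cu = _unit(chord)
    n = np.asarray(normal_pref, float)
    n = n - (n @ cu) * cu
    n = _unit(n)
    half = np.linalg.norm(chord) / 2.0
    radius = max(radius_min, half + 0.25)
    h = math.sqrt(radius ** 2 - half ** 2)
    m = 0.5 * (p + q)
    w = _unit(np.cross(n, cu))
    best = None
    for center in (m + h * w, m - h * w):
        u = _unit(p - center)
        v = np.cross(n, u)
        rel = q - center
        phi = math.atan2(float(rel @ v), float(rel @ u)) % (2 * math.pi)
        # long arc from p to q
        if phi >= math.pi:
            span, sweep = math.degrees(phi), 1
        else:
            span, sweep = math.degrees(2 * math.pi - phi), -1
        a_mid = math.radians(span / 2.0) * sweep
        mid = center + radius * (math.cos(a_mid) * u + math.sin(a_mid) * v)
        score = float(bulge_pref(mid))
        if best is None or score > best[0]:
            best = (score, center, u, span, sweep)
    _, center, u, span, sweep = best
    return center, n, radius, u, span, sweep


def make_subject(spec: SubjectSpec) -> SyntheticSubject:
    """Realize a subject: centerline polylines, eyeball meshes and ground truth."""
    import trimesh

    rng = np.random.default_rng(spec.seed)
    polylines: list[np.ndarray] = []
    key_points: dict[str, dict[str, np.ndarray]] = {}
    junctions: list[np.ndarray] = []
    ring_lengths: dict[tuple[str, str], float] = {}
    actual_normals: dict[tuple[str, str], np.ndarray] = {}

    for side in SIDES:
        a_pt = spec.crus_points[side]
        medial = _X if side == "right" else -_X  # toward the midline
        outward = -medial
        n_p = spec.normals[(side, "posterior")]
        n_s = spec.normals[(side, "superior")]
        n_h = spec.normals[(side, "lateral")]

        # superior ring: its gap faces inferiorly, so A and C both sit low and
        # the arc arches superiorly (its midpoint is the uppermost structure)
        b_dir = _project_unit(-_Z, n_s)  # in-plane "bottom" (gap center)
        best = None
        for s in (1, -1):
            u_a = _rotate_about(b_dir, n_s, -s * 60.0)
            c_dir = _rotate_about(b_dir, n_s, s * 60.0)
            anterior_gain = float((c_dir - u_a) @ _Y)
            if best is None or anterior_gain > best[0]:
                best = (anterior_gain, u_a, -s)
        _, u_a, sweep_s = best
        c_s = a_pt - _RADII["superior"] * u_a
        sup_spec = CanalSpec(true_normal=n_s, center=c_s, radius=_RADII["superior"],
                             n_points=spec.n_arc_points, noise_sd=spec.noise_sd,
                             start_direction=u_a, sweep=sweep_s)
        sup_arc = make_canal_arc(sup_spec, rng)
        sup_arc[0] = a_pt  # bitwise-exact junction anchor
        c_pt = sup_arc[-1]

        # lateral ring through C: its gap faces medially (toward the vestibule),
        # so both C and B sit medially and the ring bulges laterally; in the
        # B = D variant the gap tilts posteriorly so B falls near the crus
        bg = _project_unit(medial + (-0.5 * _Y if spec.b_equals_d else 0.2 * _Y), n_h)
        best_h = None
        for s in (1, -1):
            u_c = _rotate_about(bg, n_h, -s * 60.0)
            center = c_pt - _RADII["lateral"] * u_c
            if spec.b_equals_d:
                b_cand = center + _RADII["lateral"] * _rotate_about(bg, n_h, s * 60.0)
                score = -float(np.linalg.norm(b_cand - a_pt))
            else:
                mid = center - _RADII["lateral"] * bg
                score = float(mid @ outward)
            if best_h is None or score > best_h[0]:
                best_h = (score, u_c, -s)
        _, u_c, sweep_h = best_h
        c_h = c_pt - _RADII["lateral"] * u_c
        lat_spec = CanalSpec(true_normal=n_h, center=c_h, radius=_RADII["lateral"],
                             n_points=spec.n_arc_points, noise_sd=spec.noise_sd,
                             start_direction=u_c, sweep=sweep_h)
        lat_arc = make_canal_arc(lat_spec, rng)
        lat_arc[0] = c_pt  # bitwise-exact junction anchor
        b_pt = lat_arc[-1]

        true_n_p = n_p
        if spec.b_equals_d:
            # the posterior ring is routed through A and the lateral canal's far
            # endpoint, so the posterior ampulla and lateral canal end coincide
            d_pt = b_pt
            c_post, true_n_p, r_post, u_post, span_post, sweep_post = _ring_through_two_points(
                a_pt, d_pt, n_p, _RADII["posterior"],
                bulge_pref=lambda mid: -(mid @ _Y) - 0.5 * (mid @ _Z))
            post_spec = CanalSpec(true_normal=true_n_p, center=c_post, radius=r_post,
                                  arc_span=span_post, n_points=spec.n_arc_points,
                                  noise_sd=spec.noise_sd, start_direction=u_post,
                                  sweep=sweep_post)
            post_arc = make_canal_arc(post_spec, rng)
            post_arc[0] = a_pt
            post_arc[-1] = d_pt  # bitwise weld of the shared vestibule point
        else:
            # posterior ring: A is its topmost point, D its anterior-inferior end
            d_p = _project_unit(-_Z, n_p)
            c_p = a_pt + _RADII["posterior"] * d_p
            sweep_p, _ = _arc_endpoint_choice(c_p, _RADII["posterior"], n_p, a_pt,
                                              _ARC_SPAN, prefer=lambda p: p[1])
            post_spec = CanalSpec(true_normal=n_p, center=c_p, radius=_RADII["posterior"],
                                  n_points=spec.n_arc_points, noise_sd=spec.noise_sd,
                                  start_direction=a_pt - c_p, sweep=sweep_p)
            post_arc = make_canal_arc(post_spec, rng)
            post_arc[0] = a_pt
            d_pt = post_arc[-1]

        e_pt = 0.5 * (d_pt + c_pt) + 0.8 * _Y - 1.2 * _Z + 0.5 * medial
        cochlea_dir = _unit(1.0 * _Y - 0.3 * _Z + 0.3 * medial)
        cochlea_end = e_pt + 6.0 * cochlea_dir

        side_polys = [
            post_arc,                                      # posterior ring A–D
            sup_arc,                                       # superior ring A–C
            lat_arc,                                       # lateral ring C–B
            _line_points(a_pt, e_pt, 5, spec.noise_sd, rng),   # common crus A–E
            _line_points(d_pt, e_pt, 4, spec.noise_sd, rng),   # utricle link D–E
            _line_points(c_pt, e_pt, 4, spec.noise_sd, rng),   # utricle link C–E
            _line_points(e_pt, cochlea_end, 7, spec.noise_sd, rng),  # cochlea line
        ]
        polylines.extend(side_polys)
        key_points[side] = {"A": a_pt.copy(), "B": b_pt.copy(), "C": c_pt.copy(),
                            "D": d_pt.copy(), "E": e_pt.copy()}
        junctions.extend([a_pt.copy(), c_pt.copy(), e_pt.copy()])
        if spec.b_equals_d:
            junctions.append(d_pt.copy())
        actual_normals[(side, "posterior")] = true_n_p
        actual_normals[(side, "superior")] = n_s
        actual_normals[(side, "lateral")] = n_h
        ring_lengths[(side, "posterior")] = post_spec.radius * math.radians(post_spec.arc_span)
        ring_lengths[(side, "superior")] = sup_spec.radius * math.radians(sup_spec.arc_span)
        ring_lengths[(side, "lateral")] = lat_spec.radius * math.radians(lat_spec.arc_span)

    # eyeballs: identical meshes shifted only along x, so the fundus geometry
    # is left/right symmetric and the plane is tangent to both
    ico = trimesh.creation.icosphere(subdivisions=_EYE_SUBDIV, radius=spec.eyeball_radius)
    eyeballs = {}
    eye_meshes = {}
    for side in SIDES:
        verts = np.asarray(ico.vertices) + spec.eyeball_centers[side]
        eye_meshes[side] = (verts, np.asarray(ico.faces))

    # rigid pose applied to everything
    rot, t = spec.rotation, spec.translation
    posed_polys = [p @ rot.T + t for p in polylines]
    for side in SIDES:
        verts, faces = eye_meshes[side]
        eyeballs[side] = EyeballSurface(side=side, points=verts @ rot.T + t, faces=faces)
    truth = GroundTruth(
        normals={k: rot @ v for k, v in actual_normals.items()},
        key_points={s: {k: rot @ v + t for k, v in kp.items()}
                    for s, kp in key_points.items()},
        junctions=[rot @ j + t for j in junctions],
        ring_lengths=ring_lengths,
        rotation=rot.copy(),
        translation=t.copy(),
    )
    cset = CenterlineSet(subject_id=spec.subject_id,
                         polylines=tuple(Polyline(p) for p in posed_polys))
    return SyntheticSubject(subject_id=spec.subject_id, centerlines=cset,
                            eyeballs=eyeballs, truth=truth)


# ---------------------------------------------------------------------------
# cohorts

@dataclass(frozen=True)
class CohortSpec:
    """Generative recipe for a cohort of synthetic subjects.

    ``concentration`` maps (side, canal) to a vMF κ; ``None`` calibrates κ per
    canal so the expected angular deviation matches the reference dispersion.
    """

    n_subjects: int = 55
    population_normals: dict[tuple[str, str], np.ndarray] = field(
        default_factory=lambda: {k: _unit(v) for k, v in REFERENCE_NORMALS.items()})
    concentration: dict[tuple[str, str], float] | None = None
    noise_sd: float = 0.05
    seed: int = 0
    random_pose: bool = True

    def __post_init__(self):
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if self.concentration is not None:
            for k, kap in self.concentration.items():
                if kap <= 0:
                    raise ValueError(f"concentration for {k} must be > 0")
        object.__setattr__(self, "population_normals",
                           {k: _unit(v) for k, v in self.population_normals.items()})

    def resolved_concentration(self) -> dict[tuple[str, str], float]:
        if self.concentration is not None:
            return dict(self.concentration)
        return {k: kappa_for_mean_deviation(dev) for k, dev in REFERENCE_DEVIATION_DEG.items()}


def make_cohort(spec: CohortSpec) -> tuple[list[SyntheticSubject], dict]:
    """Generate a cohort; returns the subjects and the cohort-level ground truth."""
    rng = np.random.default_rng(spec.seed)
    kappas = spec.resolved_concentration()
    subjects = []
    drawn: dict[tuple[str, str], list[np.ndarray]] = {k: [] for k in spec.population_normals}
    for i in range(spec.n_subjects):
        normals = {}
        for key, mu in spec.population_normals.items():
            v = sample_vmf(mu, kappas[key], 1, rng)[0]
            normals[key] = v
            drawn[key].append(v)
        pose = random_rigid_pose(rng) if spec.random_pose else (np.eye(3), np.zeros(3))
        sub_seed = int(rng.integers(0, 2 ** 31 - 1))
        sspec = SubjectSpec.default(seed=sub_seed, subject_id=f"synthetic-{i:03d}",
                                    normals=normals, noise_sd=spec.noise_sd, pose=pose)
        subjects.append(make_subject(sspec))
    truth = {
        "population_normals": dict(spec.population_normals),
        "concentration": kappas,
        "drawn_normals": {k: np.array(v) for k, v in drawn.items()},
    }
    return subjects, truth
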