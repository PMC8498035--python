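"""Readers and writers for centerline polylines, eyeball surfaces and result tables.

All coordinates are in millimetres throughout; no unit conversion happens
anywhere in the package. The native centerline format is a small JSON dialect::

    {"subject_id": "s01", "units": "mm",
     "polylines": [[[x, y, z], ...], ...]}

Junction coordinates shared between polylines must be written bit-identically;
``write_centerlines``/``read_centerlines`` round-trip coordinates exactly
(Python's float repr is lossless).  A best-effort reader for VTK PolyData XML
(``.vtp``, ASCII) is provided for interoperability with centerline-extraction
tools. Eyeball surfaces are read from STL (binary or ASCII, via trimesh) or
plain ``x y z`` text files.
"""

from __future__ import annotations

import json
import logging
import xml.etree.ElementTree as ET
from dataclasses import dataclass
from pathlib import Path
import numpy as np

log = logging.getLogger(__name__)

__all__ = [
    "Polyline",
    "CenterlineSet",
    "EyeballSurface",
    "ValidationError",
    "read_centerlines",
    "write_centerlines",
    "read_eyeball",
    "write_eyeball",
    "write_summary",
    "write_summary_json",
]


class ValidationError(ValueError):
    """Raised when an input file or in-memory object violates a structural invariant."""


def _as_points(points, what: str) -> np.ndarray:
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3:
        raise ValidationError(f"{what}: expected an (N, 3) coordinate array, got shape {pts.shape}")
    if not np.isfinite(pts).all():
        raise ValidationError(f"{what}: coordinates must be finite")
    return pts


@dataclass(frozen=True)
class Polyline:
    """An ordered open polyline of 3D points (mm).

    Invariants: at least two points, consecutive points distinct.
    """

    points: np.ndarray

    def __post_init__(self):
        pts = _as_points(self.points, "Polyline")
        if len(pts) < 2:
            raise ValidationError(f"Polyline needs >= 2 points, got {len(pts)}")
        seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
        if np.any(seg == 0.0):
            raise ValidationError("Polyline has coincident consecutive points")
        object.__setattr__(self, "points", pts)

    @property
    def length(self) -> float:
        """Polygonal arc length (mm)."""
        return float(np.linalg.norm(np.diff(self.points, axis=0), axis=1).sum())


@dataclass(frozen=True)
class CenterlineSet:
    """A subject's inner-ear centerline model: a bag of polylines in image coordinates."""

    subject_id: str
    polylines: tuple[Polyline, ...]
    units: str = "mm"

    def __post_init__(self):
        polys = tuple(
            p if isinstance(p, Polyline) else Polyline(np.asarray(p, dtype=float))
            for p in self.polylines
        )
        if not polys:
            raise ValidationError("CenterlineSet needs at least one polyline")
        if self.units != "mm":
            raise ValidationError(f"units must be 'mm', got {self.units!r}")
        object.__setattr__(self, "polylines", polys)

    @property
    def n_points(self) -> int:
        return sum(len(p.points) for p in self.polylines)


@dataclass(frozen=True)
class EyeballSurface:
    """An eyeball surface as a welded point set (mm), with optional triangle faces."""

    side: str
    points: np.ndarray
    faces: np.ndarray | None = None

    def __post_init__(self):
        if self.side not in ("left", "right"):
            raise ValidationError(f"side must be 'left' or 'right', got {self.side!r}")
        pts = _as_points(self.points, "EyeballSurface")
        if len(pts) < 4:
            raise ValidationError(f"EyeballSurface needs >= 4 points, got {len(pts)}")
        # non-coplanarity: smallest principal extent of the centered cloud must be nonzero
        s = np.linalg.svd(pts - pts.mean(axis=0), compute_uv=False)
        if s[2] <= 1e-9 * max(s[0], 1.0):
            raise ValidationError("EyeballSurface points are (near-)coplanar")
        object.__setattr__(self, "points", pts)
        if self.faces is not None:
            faces = np.asarray(self.faces, dtype=int)
            if faces.ndim != 2 or faces.shape[1] != 3:
                raise ValidationError("faces must be an (M, 3) index array")
            if faces.min() < 0 or faces.max() >= len(pts):
                raise ValidationError("face indices out of range")
            object.__setattr__(self, "faces", faces)


# ---------------------------------------------------------------------------
# centerline I/O

def write_centerlines(cset: CenterlineSet, path) -> None:
    """Write a CenterlineSet in the native JSON dialect (lossless floats)."""
    doc = {
        "subject_id": cset.subject_id,
        "units": cset.units,
        "polylines": [p.points.tolist() for p in cset.polylines],
    }
    Path(path).write_text(json.dumps(doc))


def read_centerlines(path, format: str | None = None) -> CenterlineSet:
    """Read a centerline model.

    Parameters
    ----------
    path : path-like
    format : {"json", "vtp-xml", None}
        ``None`` infers from the extension (``.vtp`` → vtp-xml, else json).
    """
    path = Path(path)
    if format is None:
        format = "vtp-xml" if path.suffix.lower() == ".vtp" else "json"
    if format == "json":
        return _read_centerlines_json(path)
    if format == "vtp-xml":
        return _read_centerlines_vtp(path)
    raise ValueError(f"unknown centerline format {format!r}")


def _read_centerlines_json(path: Path) -> CenterlineSet:
    try:
        doc = json.loads(path.read_text())
    except json.JSONDecodeError as e:
        raise ValidationError(f"{path}: malformed JSON at line {e.lineno}, column {e.colno}: {e.msg}") from e
    for key in ("subject_id", "units", "polylines"):
        if key not in doc:
            raise ValidationError(f"{path}: missing required key {key!r}")
    polys = []
    for i, raw in enumerate(doc["polylines"]):
        try:
            polys.append(Polyline(np.asarray(raw, dtype=float)))
        except (ValidationError, ValueError) as e:
            raise ValidationError(f"{path}: polyline {i}: {e}") from e
    return CenterlineSet(subject_id=str(doc["subject_id"]), polylines=tuple(polys), units=doc["units"])


def _read_centerlines_vtp(path: Path) -> CenterlineSet:
    """Best-effort reader for ASCII VTK PolyData XML with <Lines> connectivity."""
    try:
        root = ET.parse(str(path)).getroot()
    except ET.ParseError as e:
        raise ValidationError(f"{path}: malformed XML: {e}") from e
    piece = root.find(".//Piece")
    if piece is None:
        raise ValidationError(f"{path}: no <Piece> element")
    pts_da = piece.find("./Points/DataArray")
    if pts_da is None or (pts_da.get("format", "ascii") != "ascii"):
        raise ValidationError(f"{path}: only ascii <Points> DataArray is supported")
    coords = np.array((pts_da.text or "").split(), dtype=float).reshape(-1, 3)
    lines = piece.find("./Lines")
    if lines is None:
        raise ValidationError(f"{path}: no <Lines> element")
    conn = offs = None
    for da in lines.findall("DataArray"):
        if da.get("Name") == "connectivity":
            conn = np.array((da.text or "").split(), dtype=int)
        elif da.get("Name") == "offsets":
            offs = np.array((da.text or "").split(), dtype=int)
    if conn is None or offs is None:
        raise ValidationError(f"{path}: <Lines> needs connectivity and offsets arrays")
    polys, start = [], 0
    for i, end in enumerate(offs):
        idx = conn[start:end]
        start = end
        if len(idx) < 2:
            raise ValidationError(f"{path}: line {i} has fewer than 2 points")
        polys.append(Polyline(coords[idx]))
    return CenterlineSet(subject_id=path.stem, polylines=tuple(polys))


# ---------------------------------------------------------------------------
# eyeball I/O

def _weld_points(pts: np.ndarray, tol: float = 1e-9) -> np.ndarray:
    """Collapse points closer than ``tol`` (mm) to a single representative."""
    from scipy.spatial import cKDTree

    if len(pts) == 0:
        return pts, np.zeros(0, dtype=int)
    tree = cKDTree(pts)
    pairs = tree.query_pairs(tol, output_type="ndarray")
    parent = np.arange(len(pts))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for a, b in pairs:
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[max(ra, rb)] = min(ra, rb)
    roots = np.array([find(i) for i in range(len(pts))])
    uniq, inverse = np.unique(roots, return_inverse=True)
    return pts[uniq], inverse


def read_eyeball(path, side: str, format: str | None = None) -> EyeballSurface:
    """Read an eyeball surface from STL (binary/ascii) or whitespace xyz text.

    STL vertices duplicated across triangles are welded at 1e-9 mm.
    """
    path = Path(path)
    if format is None:
        format = "xyz" if path.suffix.lower() == ".xyz" else "stl"
    if path.stat().st_size == 0:
        raise ValidationError(f"{path}: empty file")
    if format == "stl":
        import trimesh

        mesh = trimesh.load(str(path), file_type="stl", process=False)
        raw = np.asarray(mesh.vertices, dtype=float)
        if not np.isfinite(raw).all():
            raise ValidationError(f"{path}: non-finite coordinates")
        welded, inverse = _weld_points(raw, tol=1e-9)
        faces = inverse[np.asarray(mesh.faces, dtype=int)] if len(mesh.faces) else None
        log.info("read %s: %d raw vertices -> %d welded points", path, len(raw), len(welded))
        return EyeballSurface(side=side, points=welded, faces=faces)
    if format == "xyz":
        pts = np.loadtxt(str(path), dtype=float, ndmin=2)
        return EyeballSurface(side=side, points=pts)
    raise ValueError(f"unknown eyeball format {format!r}")


def write_eyeball(surface: EyeballSurface, path, format: str = "stl-ascii") -> None:
    """Write an eyeball surface as STL (requires faces) or xyz."""
    path = Path(path)
    if format == "xyz":
        np.savetxt(str(path), surface.points, fmt="%.9f")
        return
    if surface.faces is None:
        raise ValidationError("STL export requires triangle faces")
    import trimesh

    mesh = trimesh.Trimesh(vertices=surface.points, faces=surface.faces, process=False)
    if format == "stl-ascii":
        path.write_text(mesh.export(file_type="stl_ascii"))
    elif format == "stl-binary":
        path.write_bytes(mesh.export(file_type="stl"))
    else:
        raise ValueError(f"unknown STL format {format!r}")


# ---------------------------------------------------------------------------
# result tables

_CSV_COLUMNS = [
    "canal",
    "sagittal_deg",
    "coronal_deg",
    "horizontal_deg",
    "deviation_mean_deg",
    "deviation_sd_deg",
    "method",
]

_CANAL_CODE = {("right", "posterior"): "RP", ("right", "superior"): "RA", ("right", "lateral"): "RH",
               ("left", "posterior"): "LP", ("left", "superior"): "LA", ("left", "lateral"): "LH"}
_CANAL_ORDER = ["RP", "RA", "RH", "LP", "LA", "LH"]


def canal_code(side: str, canal: str) -> str:
    """Two-letter canal code (side R/L + canal P/A/H) used in result tables."""
    return _CANAL_CODE[(side, canal)]


def write_summary(summary, path) -> None:
    """Write a cohort summary as CSV, one row per canal per method.

    Angles and deviations are rounded to two decimals at write time only;
    the JSON mirror (:func:`write_summary_json`) keeps full precision.
    """
    import pandas as pd

    rows = []
    for (side, canal), cs in summary.groups.items():
        code = canal_code(side, canal)
        rows.append({
            "canal": code,
            "sagittal_deg": round(cs.vector_mean_angles[0], 2),
            "coronal_deg": round(cs.vector_mean_angles[1], 2),
            "horizontal_deg": round(cs.vector_mean_angles[2], 2),
            "deviation_mean_deg": round(cs.deviation_mean, 2),
            "deviation_sd_deg": round(cs.deviation_sd, 2) if cs.deviation_sd == cs.deviation_sd else "",
            "method": "vector",
        })
        rows.append({
            "canal": code,
            "sagittal_deg": round(cs.angle_mean_angles[0], 2),
            "coronal_deg": round(cs.angle_mean_angles[1], 2),
            "horizontal_deg": round(cs.angle_mean_angles[2], 2),
            "deviation_mean_deg": round(cs.deviation_mean, 2),
            "deviation_sd_deg": round(cs.deviation_sd, 2) if cs.deviation_sd == cs.deviation_sd else "",
            "method": "angle",
        })
    if not rows:
        raise ValidationError("empty summary: nothing to write")
    df = pd.DataFrame(rows, columns=_CSV_COLUMNS)
    df["__ord"] = df["canal"].map({c: i for i, c in enumerate(_CANAL_ORDER)})
    df = df.sort_values(["method", "__ord"], ascending=[False, True]).drop(columns="__ord")
    df.to_csv(path, index=False, lineterminator="\r\n")


def write_summary_json(summary, path) -> None:
    """Full-precision JSON mirror of the cohort summary."""
    doc = {}
    for (side, canal), cs in summary.groups.items():
        doc[canal_code(side, canal)] = cs.to_dict()
    Path(path).write_text(json.dumps(doc, indent=1))
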