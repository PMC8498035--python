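"""Cohort-level directional statistics for canal plane normals.

Two averaging conventions are computed side by side:

* **vector mean** — the normalized componentwise sum of the unit normals
  (the mean direction of directional statistics), whose direction angles are
  arccosines of its components;
* **angle mean** — the traditional per-axis arithmetic mean (± sample sd) of
  the individual direction angles, whose cosines assemble a generally
  non-unit vector.

The angular dispersion of a canal across subjects is summarized as the
deviation range: mean ± sd of the angles between each subject's normal and
the cohort vector-mean normal.  The discrepancy between the two averaging
conventions is the angle between the vector mean and the unit-normalized
angle-mean vector; it vanishes as the sample concentrates.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .plane import CanalAttitude, direction_angles

log = logging.getLogger(__name__)

__all__ = [
    "CanalGroupSummary",
    "CohortSummary",
    "vector_mean",
    "angle_mean",
    "deviation_range",
    "method_difference",
    "summarize_cohort",
    "export_sphere_scatter",
]


def _as_unit_rows(normals) -> np.ndarray:
    v = np.asarray(normals, dtype=float)
    if v.ndim == 1:
        v = v[None, :]
    norms = np.linalg.norm(v, axis=1)
    if np.any(np.abs(norms - 1.0) > 1e-6):
        raise ValueError("all normals must be unit vectors")
    return v


def _clamped_arccos_deg(x) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if np.any(np.abs(x) > 1.0 + 1e-9):
        raise ValueError("cosine outside [-1, 1] beyond rounding tolerance")
    return np.degrees(np.arccos(np.clip(x, -1.0, 1.0)))


def vector_mean(normals) -> np.ndarray:
    """Mean direction: the normalized sum of the unit normals."""
    v = _as_unit_rows(normals)
    s = v.sum(axis=0)
    r = np.linalg.norm(s)
    if r <= 1e-9:
        raise ValueError("resultant is (near-)zero: mean direction undefined")
    return s / r


def angle_mean(normals) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-axis arithmetic mean and sample sd of the direction angles.

    Returns ``(mean_angles_deg, sd_angles_deg, cosine_vector)`` where the
    cosine vector (cos of the three mean angles) is generally *not* unit.
    """
    v = _as_unit_rows(normals)
    if len(v) < 2:
        raise ValueError("angle_mean needs >= 2 normals for a sample sd")
    ang = _clamped_arccos_deg(v)
    mean = ang.mean(axis=0)
    sd = ang.std(axis=0, ddof=1)
    cosv = np.cos(np.radians(mean))
    return mean, sd, cosv


def deviation_range(normals, mean) -> tuple[float, float]:
    """Mean ± sd (degrees) of the angles between each normal and ``mean``."""
    v = _as_unit_rows(normals)
    if len(v) < 2:
        raise ValueError("deviation_range needs >= 2 normals")
    m = _as_unit_rows(mean)[0]
    ang = _clamped_arccos_deg(v @ m)
    return float(ang.mean()), float(ang.std(ddof=1))


def method_difference(v_vec, v_ang_unit) -> float:
    """Angle (degrees) between the two averaging conventions' unit vectors."""
    a = _as_unit_rows(v_vec)[0]
    b = _as_unit_rows(v_ang_unit)[0]
    return float(_clamped_arccos_deg(float(a @ b)))


@dataclass(frozen=True)
class CanalGroupSummary:
    """Summary statistics for one (side, canal) group."""

    side: str
    canal: str
    n: int
    vector_mean_normal: np.ndarray
    vector_mean_angles: tuple[float, float, float]
    angle_mean_angles: tuple[float, float, float]
    angle_mean_sds: tuple[float, float, float]
    angle_mean_vector: np.ndarray      # cosines of the mean angles; non-unit in general
    angle_mean_unit: np.ndarray        # unit-normalized copy
    deviation_mean: float
    deviation_sd: float
    method_difference: float

    def to_dict(self) -> dict:
        return {
            "side": self.side,
            "canal": self.canal,
            "n": self.n,
            "vector_mean_normal": np.asarray(self.vector_mean_normal).tolist(),
            "vector_mean_angles_deg": list(self.vector_mean_angles),
            "angle_mean_angles_deg": list(self.angle_mean_angles),
            "angle_mean_sds_deg": list(self.angle_mean_sds),
            "angle_mean_vector": np.asarray(self.angle_mean_vector).tolist(),
            "angle_mean_unit": np.asarray(self.angle_mean_unit).tolist(),
            "deviation_mean_deg": self.deviation_mean,
            "deviation_sd_deg": self.deviation_sd,
            "method_difference_deg": self.method_difference,
        }


@dataclass
class CohortSummary:
    """Per-(side, canal) group summaries plus completeness warnings."""

    groups: dict[tuple[str, str], CanalGroupSummary]
    warnings: list[str] = field(default_factory=list)


def summarize_cohort(attitudes: list[CanalAttitude],
                     expected_groups=None) -> CohortSummary:
    """Aggregate per-subject canal attitudes into a cohort summary.

    For each (side, canal) group: vector mean (with its direction angles),
    per-axis angle mean ± sd, deviation range against the vector mean, and
    the vector-vs-angle method difference.  With a single subject the sds and
    deviation range are NaN and a warning is recorded.
    """
    by_group: dict[tuple[str, str], list[np.ndarray]] = {}
    for att in attitudes:
        by_group.setdefault((att.side, att.canal), []).append(np.asarray(att.unit_normal))
    warnings = []
    if expected_groups:
        missing = [g for g in expected_groups if g not in by_group]
        for g in missing:
            warnings.append(f"missing group {g}; omitted from summary")
    groups = {}
    for key, normals in sorted(by_group.items()):
        v = np.array(normals)
        vm = vector_mean(v)
        vm_angles = direction_angles(vm, unit_tol=1e-9)
        if len(v) >= 2:
            am, asd, cosv = angle_mean(v)
            dev_mean, dev_sd = deviation_range(v, vm)
        else:
            warnings.append(f"group {key}: single subject; sds and deviation range undefined")
            am = np.array(direction_angles(v[0], unit_tol=1e-6))
            asd = np.full(3, np.nan)
            cosv = np.cos(np.radians(am))
            dev_mean, dev_sd = math.nan, math.nan
        am_unit = cosv / np.linalg.norm(cosv)
        groups[key] = CanalGroupSummary(
            side=key[0], canal=key[1], n=len(v),
            vector_mean_normal=vm,
            vector_mean_angles=tuple(float(a) for a in vm_angles),
            angle_mean_angles=tuple(float(a) for a in am),
            angle_mean_sds=tuple(float(a) for a in asd),
            angle_mean_vector=cosv,
            angle_mean_unit=am_unit,
            deviation_mean=dev_mean,
            deviation_sd=dev_sd,
            method_difference=method_difference(vm, am_unit),
        )
    return CohortSummary(groups=groups, warnings=warnings)


def export_sphere_scatter(normals_by_group: dict, means_by_group: dict, path,
                          radius: float = 100.0, json_path=None) -> None:
    """Sphere-scatter display of the normal-vector distribution.

    Each group's unit normals are scaled to the given radius and drawn as a
    color group; group means are drawn as arrows from the origin.  A JSON
    companion with the exact points and arrows is written for headless
    inspection.
    """
    if not normals_by_group:
        raise ValueError("need at least one group of normals")
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig = plt.figure(figsize=(7, 7))
    ax = fig.add_subplot(projection="3d")
    doc = {"radius": radius, "groups": {}}
    colors = plt.cm.tab10.colors
    for i, (key, normals) in enumerate(sorted(normals_by_group.items())):
        pts = _as_unit_rows(normals) * radius
        name = "-".join(key) if isinstance(key, tuple) else str(key)
        color = colors[i % len(colors)]
        ax.scatter(pts[:, 0], pts[:, 1], pts[:, 2], s=8, color=color, label=name)
        entry = {"points": pts.tolist()}
        if key in means_by_group:
            m = _as_unit_rows(means_by_group[key])[0] * radius
            ax.quiver(0, 0, 0, m[0], m[1], m[2], color=color, arrow_length_ratio=0.06)
            entry["arrow"] = m.tolist()
        doc["groups"][name] = entry
    ax.set_xlabel("x (left)")
    ax.set_ylabel("y (anterior)")
    ax.set_zlabel("z (superior)")
    ax.legend(loc="upper left", fontsize=8)
    fig.savefig(path, dpi=120)
    plt.close(fig)
    if json_path is not None:
        Path(json_path).write_text(json.dumps(doc))
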