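"""End-to-end measurement pipeline: centerlines + eyeballs → canal attitudes.

Per subject the stages are:

1. junction detection and segment extraction on the centerline polylines,
2. splitting the segments into the two labyrinths (connected components),
3. locating each side's common-crus bifurcation (label-free: the endpoint
   shared by the two longest ring segments),
4. building the standard head frame from the two crus bifurcations and the
   eyeball fundus point,
5. canal identification and key-point labeling in the standard frame,
6. spline resampling + orthogonal least-squares plane fit per canal, giving
   unit normals and direction angles in the frame.

Cohort-level summaries (vector mean vs angle mean, deviation ranges, method
differences) are computed by :mod:`canalpose.stats`.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from . import graph, io, stats, synthetic
from .frame import FundusResult, HeadFrame, build_frame, fundus_point, to_frame
from .plane import DEFAULT_N_OUT, CanalAttitude, canal_attitude

log = logging.getLogger(__name__)

__all__ = ["AnalysisParams", "SubjectResult", "RunConfig", "measure_subject", "run_pipeline"]


@dataclass(frozen=True)
class AnalysisParams:
    """Tunable thresholds of the geometric pipeline (all in mm unless noted)."""

    weld_tol: float = graph.DEFAULT_WELD_TOL
    min_junction_separation: float = graph.DEFAULT_MIN_JUNCTION_SEP
    min_arc: float = graph.DEFAULT_MIN_ARC
    n_out: int = DEFAULT_N_OUT             # spline resample count (dimensionless)
    max_iter: int = 100                    # fundus fixed-point iteration cap
    convention_tag: str = "las"

    def __post_init__(self):
        if self.weld_tol < 0 or self.min_junction_separation <= 0 or self.min_arc <= 0:
            raise ValueError("thresholds must be positive (weld_tol may be zero)")
        if self.n_out < 10 or self.max_iter < 1:
            raise ValueError("n_out must be >= 10 and max_iter >= 1")


@dataclass
class SubjectResult:
    """Everything measured for one subject."""

    subject_id: str
    frame: HeadFrame
    fundus: FundusResult
    sides: dict[str, graph.SideAnatomy]
    attitudes: list[CanalAttitude]
    key_points_frame: dict[str, dict[str, np.ndarray]]
    warnings: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "subject_id": self.subject_id,
            "frame": self.frame.to_dict(),
            "fundus_point": self.fundus.point.tolist(),
            "fundus_iterations": self.fundus.iterations,
            "fundus_side": self.fundus.side,
            "attitudes": [a.to_dict() for a in self.attitudes],
            "key_points_frame": {s: {k: v.tolist() for k, v in kp.items()}
                                 for s, kp in self.key_points_frame.items()},
            "warnings": self.warnings,
        }


def measure_subject(cset: io.CenterlineSet, eyeballs, params: AnalysisParams | None = None,
                    subject_id: str | None = None) -> SubjectResult:
    """Measure all six canal attitudes of one subject.

    ``eyeballs`` is an iterable of :class:`~canalpose.io.EyeballSurface`
    (both eyes).  Raises :class:`~canalpose.graph.TopologyError` if the
    centerlines do not form two labyrinths.
    """
    params = params or AnalysisParams()
    eyeballs = list(eyeballs)
    subject_id = subject_id or cset.subject_id

    junctions = graph.find_junctions(cset, weld_tol=params.weld_tol,
                                     min_separation=params.min_junction_separation)
    junctions = graph.filter_junctions(cset, junctions, min_arc=params.min_arc,
                                       weld_tol=params.weld_tol)
    segments = graph.extract_segments(cset, junctions, weld_tol=params.weld_tol)
    components = graph.split_components(segments, weld_tol=params.weld_tol)
    if len(components) != 2:
        raise graph.TopologyError(
            f"expected 2 labyrinths (connected components), found {len(components)}")

    crus = [graph.crus_bifurcation(segments, comp, min_arc=params.min_arc,
                                   weld_tol=params.weld_tol) for comp in components]
    sup_hint = graph.superior_hint(segments, components, min_arc=params.min_arc)
    fundus = fundus_point(eyeballs, crus[0], crus[1], max_iter=params.max_iter,
                          superior_hint=sup_hint)

    # anterior reference: the eyeballs lie anterior to the labyrinths
    eye_centroid = np.vstack([e.points for e in eyeballs]).mean(axis=0)
    crus_mid = 0.5 * (crus[0] + crus[1])
    z = fundus.plane.normal
    anterior = eye_centroid - crus_mid
    anterior = anterior - (anterior @ z) * z
    x_cand = crus[0] - crus[1]
    x_cand = x_cand - (x_cand @ z) * z
    # the crus whose direction makes Z×X point toward the eyes is the left one
    if float(np.cross(z, x_cand) @ anterior) > 0:
        crus_left, crus_right = crus[0], crus[1]
        comp_left, comp_right = components[0], components[1]
    else:
        crus_left, crus_right = crus[1], crus[0]
        comp_left, comp_right = components[1], components[0]

    frame = build_frame(crus_left, crus_right, fundus.plane,
                        convention_tag=params.convention_tag)

    warnings: list[str] = []
    if not fundus.converged:
        warnings.append("fundus iteration did not converge; deepest vertex kept")
    sides: dict[str, graph.SideAnatomy] = {}
    attitudes: list[CanalAttitude] = []
    key_points_frame: dict[str, dict[str, np.ndarray]] = {}
    for side, comp in (("left", comp_left), ("right", comp_right)):
        anatomy = graph.identify_side(segments, comp, frame, side,
                                      min_arc=params.min_arc, weld_tol=params.weld_tol)
        sides[side] = anatomy
        warnings.extend(f"{side}: {w}" for w in anatomy.warnings)
        for canal, labeled in anatomy.canals.items():
            arc_f = to_frame(labeled.arc, frame)
            attitudes.append(canal_attitude(side, canal, arc_f, n_out=params.n_out))
        key_points_frame[side] = {k: to_frame(v, frame)
                                  for k, v in anatomy.key_points.as_dict().items()}
    return SubjectResult(subject_id=subject_id, frame=frame, fundus=fundus,
                         sides=sides, attitudes=attitudes,
                         key_points_frame=key_points_frame, warnings=warnings)


# ---------------------------------------------------------------------------
# batch runner

@dataclass
class RunConfig:
    """Configuration of a full pipeline run (mirrors the CLI flags)."""

    output_dir: Path
    centerline_paths: list[Path] = field(default_factory=list)
    eyeball_paths: dict[str, dict[str, Path]] = field(default_factory=dict)  # subject -> side -> path
    simulate_n: int = 0
    seed: int | None = None
    noise_sd: float = 0.05
    params: AnalysisParams = field(default_factory=AnalysisParams)
    make_plot: bool = True

    def __post_init__(self):
        self.output_dir = Path(self.output_dir)
        if self.simulate_n and self.seed is None:
            raise ValueError("simulate requires a seed")


def _write_json(path: Path, doc) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(doc, indent=1))


def simulate_cohort(config: RunConfig) -> list[synthetic.SyntheticSubject]:
    """Generate and persist a synthetic cohort under ``output_dir/subjects``."""
    spec = synthetic.CohortSpec(n_subjects=config.simulate_n, seed=config.seed,
                                noise_sd=config.noise_sd)
    subjects, _ = synthetic.make_cohort(spec)
    subdir = config.output_dir / "subjects"
    subdir.mkdir(parents=True, exist_ok=True)
    for sub in subjects:
        io.write_centerlines(sub.centerlines, subdir / f"{sub.subject_id}.json")
        for side, eye in sub.eyeballs.items():
            io.write_eyeball(eye, subdir / f"{sub.subject_id}_{side}.stl", format="stl-ascii")
        truth_doc = {
            "normals": {f"{s}-{c}": v.tolist() for (s, c), v in sub.truth.normals.items()},
            "key_points": {s: {k: v.tolist() for k, v in kp.items()}
                           for s, kp in sub.truth.key_points.items()},
        }
        _write_json(subdir / f"{sub.subject_id}_truth.json", truth_doc)
    return subjects


def run_pipeline(config: RunConfig) -> stats.CohortSummary:
    """Run all stages and write per-stage artifacts; returns the cohort summary."""
    out = config.output_dir
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=logging.INFO)

    if config.simulate_n:
        subjects = simulate_cohort(config)
        inputs = [(s.subject_id, s.centerlines, list(s.eyeballs.values())) for s in subjects]
    else:
        if not config.centerline_paths:
            raise ValueError("no inputs: provide centerline paths or simulate_n")
        inputs = []
        for cpath in config.centerline_paths:
            cset = io.read_centerlines(cpath)
            sid = cset.subject_id
            eyes = []
            for side, epath in config.eyeball_paths.get(sid, {}).items():
                eyes.append(io.read_eyeball(epath, side=side))
            if not eyes:
                raise ValueError(f"subject {sid}: no eyeball surfaces configured")
            inputs.append((sid, cset, eyes))

    attitudes = []
    resdir = out / "results"
    resdir.mkdir(parents=True, exist_ok=True)
    for sid, cset, eyes in inputs:
        try:
            result = measure_subject(cset, eyes, params=config.params, subject_id=sid)
        except Exception as e:
            raise RuntimeError(f"stage 'measure' failed for subject {sid}: {e}") from e
        _write_json(resdir / f"{sid}_attitude.json", result.to_dict())
        attitudes.extend(result.attitudes)

    summary = stats.summarize_cohort(
        attitudes, expected_groups=[(s, c) for s in ("right", "left")
                                    for c in ("posterior", "superior", "lateral")])
    io.write_summary(summary, out / "summary.csv")
    io.write_summary_json(summary, out / "summary.json")
    if config.make_plot:
        normals_by_group = {}
        for att in attitudes:
            normals_by_group.setdefault((att.side, att.canal), []).append(att.unit_normal)
        means = {k: g.vector_mean_normal for k, g in summary.groups.items()}
        stats.export_sphere_scatter(normals_by_group, means, out / "normals_sphere.png",
                                    json_path=out / "normals_sphere.json")
    run_log = {
        "n_subjects": len(inputs),
        "params": asdict(config.params),
        "seed": config.seed,
        "warnings": summary.warnings,
    }
    _write_json(out / "run_log.json", run_log)
    return summary
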