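import math

import numpy as np
import pytest

from canalpose.plane import CanalAttitude, direction_angles
from canalpose.stats import (
    angle_mean,
    deviation_range,
    method_difference,
    summarize_cohort,
    vector_mean,
)
from canalpose.synthetic import sample_vmf


def _unit(v):
    v = np.asarray(v, float)
    return v / np.linalg.norm(v)


class TestVectorMean:
    def test_identical_vectors(self):
        v = _unit([0.2, 0.5, 0.9])
        assert np.allclose(vector_mean([v, v, v]), v, atol=1e-15)

    def test_symmetric_pair(self):
        m = vector_mean([[1.0, 0, 0], [0.0, 1, 0]])
        assert np.allclose(m, [math.sqrt(2) / 2, math.sqrt(2) / 2, 0])

    def test_matches_summation_oracle(self, rng):
        draws = sample_vmf(_unit([0.1, 0.3, 0.9]), 50.0, 100, rng)
        # independent componentwise accumulation
        acc = [0.0, 0.0, 0.0]
        for d in draws:
            for i in range(3):
                acc[i] += float(d[i])
        norm = math.sqrt(sum(a * a for a in acc))
        oracle = np.array([a / norm for a in acc])
        assert np.allclose(vector_mean(draws), oracle, atol=1e-14)

    def test_order_and_duplication_invariance(self, rng):
        draws = sample_vmf(_unit([0.5, 0.5, 0.7]), 30.0, 40, rng)
        m1 = vector_mean(draws)
        m2 = vector_mean(draws[::-1])
        m3 = vector_mean(np.vstack([draws, draws]))
        assert np.allclose(m1, m2, atol=1e-14)
        assert np.allclose(m1, m3, atol=1e-14)

    def test_near_zero_resultant_rejected(self):
        with pytest.raises(ValueError, match="resultant"):
            vector_mean([[0.0, 0, 1], [0.0, 0, -1]])


class TestAngleMean:
    def test_identical_vectors_have_zero_sd(self):
        v = _unit([0.3, -0.4, 0.86])
        mean, sd, cosv = angle_mean([v, v, v])
        assert np.allclose(mean, direction_angles(v, unit_tol=1e-9))
        assert np.allclose(sd, 0)
        assert np.allclose(cosv, v, atol=1e-12)

    def test_hand_computed_example(self):
        mean, sd, cosv = angle_mean([[1.0, 0, 0], [0.0, 1, 0]])
        assert np.allclose(mean, [45, 45, 90])
        assert np.allclose(cosv, [math.sqrt(2) / 2, math.sqrt(2) / 2, 0], atol=1e-12)

    def test_matches_independent_oracle(self, rng):
        draws = sample_vmf(_unit([0.2, 0.6, 0.75]), 80.0, 60, rng)
        mean, sd, cosv = angle_mean(draws)
        for axis in range(3):
            angles = [math.degrees(math.acos(max(-1.0, min(1.0, float(d[axis])))))
                      for d in draws]
            mu = sum(angles) / len(angles)
            var = sum((a - mu) ** 2 for a in angles) / (len(angles) - 1)
            assert mean[axis] == pytest.approx(mu, abs=1e-12)
            assert sd[axis] == pytest.approx(math.sqrt(var), abs=1e-12)

    def test_single_vector_rejected(self):
        with pytest.raises(ValueError, match=">= 2"):
            angle_mean([[0.0, 0, 1]])


class TestDeviationRange:
    def test_all_equal_gives_zero(self):
        v = _unit([0.1, 0.2, 0.97])
        mean_deg, sd_deg = deviation_range([v, v, v], v)
        assert mean_deg == pytest.approx(0, abs=1e-6)
        assert sd_deg == pytest.approx(0, abs=1e-6)

    def test_symmetric_ten_degree_pair(self):
        mean = np.array([0.0, 0, 1])
        a = np.array([math.sin(math.radians(10)), 0, math.cos(math.radians(10))])
        b = np.array([-math.sin(math.radians(10)), 0, math.cos(math.radians(10))])
        mean_deg, sd_deg = deviation_range([a, b], mean)
        assert mean_deg == pytest.approx(10.0, abs=1e-9)
        assert sd_deg == pytest.approx(0.0, abs=1e-9)

    def test_vector_mean_nearly_minimizes_mean_deviation(self, rng):
        draws = sample_vmf(_unit([0.4, 0.2, 0.89]), 50.0, 100, rng)
        m = vector_mean(draws)
        base, _ = deviation_range(draws, m)
        for _ in range(1000):
            other = rng.normal(size=3)
            other /= np.linalg.norm(other)
            alt, _ = deviation_range(draws, other)
            assert base <= alt + 1e-9


class TestMethodDifference:
    def test_identical_and_antipodal(self):
        v = _unit([0.3, 0.3, 0.9])
        assert method_difference(v, v) == pytest.approx(0.0, abs=1e-6)
        assert method_difference(v, -v) == pytest.approx(180.0, abs=1e-6)

    def test_vanishes_for_concentrated_cohorts(self, rng):
        mu = _unit([-0.651, 0.702, 0.287])
        draws = sample_vmf(mu, 1e6, 55, rng)
        vm = vector_mean(draws)
        _, _, cosv = angle_mean(draws)
        assert method_difference(vm, cosv / np.linalg.norm(cosv)) < 0.01

    def test_angle_mean_norm_approaches_one_with_concentration(self, rng):
        mu = _unit([0.2, -0.3, 0.93])
        norms = []
        for kappa in (10.0, 100.0, 1000.0, 10000.0):
            draws = sample_vmf(mu, kappa, 500, rng)
            _, _, cosv = angle_mean(draws)
            norms.append(np.linalg.norm(cosv))
        assert all(b > a for a, b in zip(norms, norms[1:]))
        assert norms[-1] == pytest.approx(1.0, abs=1e-3)


class TestSummarizeCohort:
    def _attitudes(self, normals_by_key):
        atts = []
        for (side, canal), normals in normals_by_key.items():
            for v in normals:
                v = np.asarray(v, float)
                atts.append(CanalAttitude(side=side, canal=canal, unit_normal=v,
                                          direction_angles=direction_angles(v, unit_tol=1e-6),
                                          fit_rms=0.0))
        return atts

    def test_identical_subjects_give_zero_deviation(self):
        v = _unit([-0.651, 0.702, 0.287])
        summary = summarize_cohort(self._attitudes({("right", "posterior"): [v] * 5}))
        g = summary.groups[("right", "posterior")]
        assert np.allclose(g.vector_mean_normal, v, atol=1e-12)
        assert g.deviation_mean == pytest.approx(0, abs=1e-6)
        assert g.method_difference == pytest.approx(0, abs=1e-6)

    def test_single_subject_flags_undefined_sds(self):
        v = _unit([0.5, 0.5, 0.7])
        summary = summarize_cohort(self._attitudes({("left", "lateral"): [v]}))
        g = summary.groups[("left", "lateral")]
        assert math.isnan(g.deviation_sd)
        assert any("single subject" in w for w in summary.warnings)

    def test_missing_group_warned(self):
        v = _unit([0.5, 0.5, 0.7])
        summary = summarize_cohort(
            self._attitudes({("left", "lateral"): [v, v]}),
            expected_groups=[("left", "lateral"), ("right", "lateral")])
        assert any("missing group" in w for w in summary.warnings)


class TestSphereScatter:
    def test_json_companion_matches_input(self, tmp_path, rng):
        from canalpose.stats import export_sphere_scatter
        import json

        groups = {("right", "lateral"): sample_vmf(_unit([0, 0, 1]), 100.0, 7, rng),
                  ("left", "lateral"): sample_vmf(_unit([0, 0.2, 0.98]), 100.0, 5, rng)}
        means = {k: vector_mean(v) for k, v in groups.items()}
        png = tmp_path / "sphere.png"
        js = tmp_path / "sphere.json"
        export_sphere_scatter(groups, means, png, json_path=js)
        assert png.exists()
        doc = json.loads(js.read_text())
        assert len(doc["groups"]) == 2
        total = sum(len(g["points"]) for g in doc["groups"].values())
        assert total == 12
        for g in doc["groups"].values():
            assert np.allclose(np.linalg.norm(g["arrow"]), 100.0)
    def test_single_vector_scaled_to_radius(self, tmp_path):
        from canalpose.stats import export_sphere_scatter
        import json

        js = tmp_path / "one.json"
        export_sphere_scatter({"g": [[0.0, 0, 1]]}, {"g": [0.0, 0, 1]},
                              tmp_path / "one.png", json_path=js)
        doc = json.loads(js.read_text())
        assert np.allclose(doc["groups"]["g"]["points"][0], [0, 0, 100])
        assert np.allclose(doc["groups"]["g"]["arrow"], [0, 0, 100])
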