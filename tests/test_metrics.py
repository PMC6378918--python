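"""RDMS closed forms and ischemic-lesion detection algebra."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ecgikit.geometry import LesionSpec, TriangleMesh, icosphere
from ecgikit.metrics import (
    contrast_timestep,
    detect_ischemia,
    detection_threshold,
    rdms,
    rdms_summary,
    real_lesion_mask,
    score_detection,
    traffic_light,
    traffic_light_labels,
)
from ecgikit.sources import PotentialField


@pytest.fixture(scope="module")
def toy_mesh():
    """Four disjoint triangles with areas 1, 1, 2, 2."""
    verts = []
    faces = []
    for i, area in enumerate([1.0, 1.0, 2.0, 2.0]):
        base = len(verts)
        verts += [
            [10.0 * i, 0.0, 0.0],
            [10.0 * i + 2.0, 0.0, 0.0],
            [10.0 * i, area, 0.0],
        ]
        faces.append([base, base + 1, base + 2])
    return TriangleMesh(np.asarray(verts, dtype=float), np.asarray(faces))


class TestRDMS:
    def test_closed_forms(self):
        x = np.array([3.0, -1.0, 2.0])
        assert rdms(x, x) == pytest.approx(0.0, abs=1e-12)
        assert rdms(x, 5.0 * x) == pytest.approx(0.0, abs=1e-12)
        assert rdms(x, -x) == pytest.approx(2.0, abs=1e-12)
        assert rdms([1.0, 0.0], [0.0, 1.0]) == pytest.approx(np.sqrt(2.0), abs=1e-12)

    def test_literal_squared_form(self):
        x = np.array([1.0, 2.0])
        assert rdms(x, -x, root=False) == pytest.approx(4.0, abs=1e-12)

    def test_zero_norm_rejected(self):
        with pytest.raises(ValueError):
            rdms(np.zeros(3), np.ones(3))

    @given(st.integers(min_value=0, max_value=200))
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_bounded_and_zero_iff_positive_scaling(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=6)
        y = rng.normal(size=6)
        if np.linalg.norm(x) == 0 or np.linalg.norm(y) == 0:
            return
        val = rdms(x, y)
        assert 0.0 <= val <= 2.0 + 1e-12
        assert rdms(x, np.pi * x) < 1e-10


class TestRDMSSummary:
    def test_identical_fields(self):
        f = PotentialField(np.random.default_rng(0).normal(size=(8, 5)))
        s = rdms_summary(f, f)
        assert s.mean == pytest.approx(0.0, abs=1e-12)
        assert s.sd == pytest.approx(0.0, abs=1e-12)
        assert len(s.per_timestep) == 5

    def test_spatial_matches_naive_loop(self):
        rng = np.random.default_rng(1)
        a = PotentialField(rng.normal(size=(10, 6)))
        b = PotentialField(rng.normal(size=(10, 6)))
        s = rdms_summary(a, b, mode="spatial")
        naive = [rdms(a.values[:, j], b.values[:, j]) for j in range(6)]
        np.testing.assert_allclose(s.per_timestep, naive)
        assert s.mean == pytest.approx(np.mean(naive))

    def test_temporal_mode_per_node(self):
        rng = np.random.default_rng(2)
        a = PotentialField(rng.normal(size=(7, 9)))
        b = PotentialField(rng.normal(size=(7, 9)))
        s = rdms_summary(a, b, mode="temporal")
        assert len(s.per_timestep) == 7

    def test_zero_column_excluded_with_warning(self):
        a = PotentialField(np.ones((4, 3)))
        vals = np.ones((4, 3))
        vals[:, 1] = 0.0
        b = PotentialField(vals)
        with pytest.warns(UserWarning):
            s = rdms_summary(a, b)
        assert np.isnan(s.per_timestep[1])
        assert s.mean == pytest.approx(0.0, abs=1e-12)


class TestDetectionThreshold:
    def test_arithmetic_cases(self):
        w = np.array([20.0, 0.0])  # mean 10, min 0
        assert detection_threshold(w, 0.4) == pytest.approx(6.0)
        assert detection_threshold(w, 0.5) == pytest.approx(5.0)

    def test_flat_field_detects_nothing(self, toy_mesh):
        field = PotentialField(np.full((toy_mesh.n_vertices, 1), 3.0))
        report = detect_ischemia(field, toy_mesh, q=0.4, t_detect=0.0)
        assert detection_threshold(field.values[:, 0], 0.4) == pytest.approx(3.0)
        assert not report.detected_elements.any()

    def test_q_zero_threshold_is_mean(self):
        w = np.array([1.0, 2.0, 3.0])
        assert detection_threshold(w, 0.0) == pytest.approx(2.0)


class TestDetectIschemia:
    def test_uniform_field_no_detection(self):
        heart = icosphere(10.0, 1)
        field = PotentialField(np.full((heart.n_vertices, 2), -85.0))
        report = detect_ischemia(field, heart, t_detect=0.0)
        assert report.detected_elements.sum() == 0

    def test_detected_area_non_increasing_in_q(self):
        heart = icosphere(10.0, 2)
        rng = np.random.default_rng(3)
        field = PotentialField(rng.normal(size=(heart.n_vertices, 1)))
        areas = heart.face_areas()
        detected = [
            areas[detect_ischemia(field, heart, q=q, t_detect=0.0).detected_elements].sum()
            for q in (0.3, 0.4, 0.5)
        ]
        assert detected[0] >= detected[1] >= detected[2]

    def test_contrast_timestep_picks_largest_range(self):
        vals = np.zeros((5, 4))
        vals[0, 2] = -50.0  # deep minimum at t index 2
        f = PotentialField(vals)
        assert contrast_timestep(f) == 2
        assert contrast_timestep(f, window=(0.0, 1.0)) in (0, 1)


class TestTrafficLight:
    def test_perfect_and_empty_detection(self, toy_mesh):
        real = np.array([True, False, True, False])
        assert traffic_light(real, real, toy_mesh) == pytest.approx((100.0, 0.0, 0.0))
        assert traffic_light(real, np.zeros(4, bool), toy_mesh) == pytest.approx(
            (0.0, 100.0, 0.0)
        )

    def test_hand_computed_toy_case(self, toy_mesh):
        # areas (1, 1, 2, 2); real = faces {0, 2} (area 3); detected = {2, 3}
        real = np.array([True, False, True, False])
        detected = np.array([False, False, True, True])
        ci, ih, ii = traffic_light(real, detected, toy_mesh)
        assert ci == pytest.approx(200.0 / 3.0)
        assert ih == pytest.approx(100.0 / 3.0)
        assert ii == pytest.approx(200.0 / 3.0)

    def test_ii_can_exceed_100(self, toy_mesh):
        real = np.array([True, False, False, False])  # area 1
        detected = np.array([True, True, True, True])  # extra area 5
        _, _, ii = traffic_light(real, detected, toy_mesh)
        assert ii == pytest.approx(500.0)

    def test_empty_real_lesion_rejected(self, toy_mesh):
        with pytest.raises(ValueError):
            traffic_light(np.zeros(4, bool), np.ones(4, bool), toy_mesh)

    @given(st.integers(min_value=0, max_value=500))
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_ci_plus_ih_exactly_100(self, toy_mesh, seed):
        rng = np.random.default_rng(seed)
        real = rng.random(4) < 0.6
        if not real.any():
            real[0] = True
        detected = rng.random(4) < 0.5
        ci, ih, _ = traffic_light(real, detected, toy_mesh)
        assert ci + ih == pytest.approx(100.0, abs=1e-9)

    def test_labels(self):
        real = np.array([True, True, False, False])
        det = np.array([True, False, True, False])
        np.testing.assert_array_equal(traffic_light_labels(real, det), [1, 2, 3, 0])


class TestRealLesionMask:
    def test_mask_matches_centroid_distance(self):
        heart = icosphere(30.0, 2)
        centre = heart.vertices[0]
        lesion = LesionSpec(centre, 12.0)
        mask = real_lesion_mask(heart, lesion)
        d = np.linalg.norm(heart.face_centroids() - centre, axis=1)
        np.testing.assert_array_equal(mask, d <= 12.0)
        assert 0 < mask.sum() < heart.n_faces

    def test_score_detection_fills_report(self):
        heart = icosphere(30.0, 2)
        centre = heart.vertices[0]
        lesion = LesionSpec(centre, 12.0)
        mask = real_lesion_mask(heart, lesion)
        vals = np.full((heart.n_vertices, 1), 10.0)
        vals[np.linalg.norm(heart.vertices - centre, axis=1) <= 12.0] = -50.0
        report = detect_ischemia(PotentialField(vals), heart, t_detect=0.0)
        score_detection(report, mask, heart)
        assert report.ci_pct > 50.0
        assert report.ci_pct + report.ih_pct == pytest.approx(100.0, abs=1e-9)
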