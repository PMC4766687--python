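"""SVD rigid fitting, condition numbers and out-of-plane augmentation."""

import numpy as np
import pytest
import scipy.optimize

import ctmigration as cm
from ctmigration.registration import (
    OUT_OF_PLANE_LABEL,
    DegenerateConfigurationError,
)

from conftest import random_rigid


def _rss_oracle(source, destination):
    """Brute-force numerical optimizer over 6 rigid parameters."""

    def residual(params):
        t = cm.RigidTransform.from_euler(params[:3], params[3:])
        return (destination.points - t.transform_points(source.points)).ravel()

    sol = scipy.optimize.least_squares(residual, np.zeros(6), method="lm")
    return float(np.sum(sol.fun**2))


class TestFitRigid:
    def test_self_fit_is_identity(self, noncoplanar_set):
        t, report = cm.fit_rigid(noncoplanar_set, noncoplanar_set)
        assert t.is_identity(tol=1e-12)
        assert np.allclose(report.errors_3d, 0.0, atol=1e-12)

    def test_pure_lateral_shift(self, noncoplanar_set):
        # A 2-mm lateral displacement comes back as exactly that.
        shifted = cm.apply(
            cm.RigidTransform.from_translation([2, 0, 0]), noncoplanar_set
        )
        t, report = cm.fit_rigid(noncoplanar_set, shifted)
        assert np.allclose(t.rotation, np.eye(3), atol=1e-12)
        assert np.allclose(t.translation, [2, 0, 0], atol=1e-12)
        assert report.mean_error < 1e-12

    def test_recovers_seeded_transform(self, rng, noncoplanar_set):
        truth = random_rigid(rng)
        destination = cm.apply(truth, noncoplanar_set)
        t, report = cm.fit_rigid(noncoplanar_set, destination)
        assert np.allclose(t.rotation, truth.rotation, atol=1e-9)
        assert np.allclose(t.translation, truth.translation, atol=1e-9)
        assert report.mean_error < 1e-9

    def test_mirror_image_never_yields_reflection(self, noncoplanar_set):
        mirrored = noncoplanar_set.with_points(
            noncoplanar_set.points * np.array([-1.0, 1.0, 1.0])
        )
        t, report = cm.fit_rigid(noncoplanar_set, mirrored)
        assert np.linalg.det(t.rotation) == pytest.approx(1.0, abs=1e-9)
        assert report.mean_error > 0.1

    def test_matches_numerical_optimizer(self, rng):
        for _ in range(20):
            src = cm.LandmarkSet(
                tuple(f"b{i}" for i in range(9)), rng.normal(0, 30, (9, 3))
            )
            truth = random_rigid(rng, max_deg=20.0, max_t=10.0)
            noisy = cm.apply(truth, src).points + rng.normal(0, 0.1, (9, 3))
            dst = src.with_points(noisy)
            t, report = cm.fit_rigid(src, dst)
            rss = float(np.sum(report.residuals**2))
            assert rss <= _rss_oracle(src, dst) + 1e-6

    def test_equivariance_under_pre_rotation(self, rng, noncoplanar_set):
        truth = random_rigid(rng, max_deg=20.0)
        dst = cm.apply(truth, noncoplanar_set)
        q = random_rigid(rng, max_deg=60.0)
        t0, r0 = cm.fit_rigid(noncoplanar_set, dst)
        t1, r1 = cm.fit_rigid(
            cm.apply(q, noncoplanar_set), cm.apply(q, dst)
        )
        conj = cm.compose(cm.compose(q, t0), q.inverse())
        assert np.allclose(t1.rotation, conj.rotation, atol=1e-9)
        assert np.allclose(t1.translation, conj.translation, atol=1e-8)
        assert np.allclose(r0.errors_3d, r1.errors_3d, atol=1e-9)

    def test_zero_error_iff_exactly_rigid(self, rng, noncoplanar_set):
        dst = cm.apply(random_rigid(rng), noncoplanar_set)
        _, exact = cm.fit_rigid(noncoplanar_set, dst)
        assert np.all(exact.errors_3d < 1e-9)
        bent = dst.points.copy()
        bent[0] += [0.5, 0, 0]
        _, inexact = cm.fit_rigid(noncoplanar_set, dst.with_points(bent))
        assert inexact.mean_error > 1e-3

    def test_length_mismatch_and_too_few_points(self, noncoplanar_set):
        with pytest.raises(ValueError, match="mismatch"):
            cm.fit_rigid(noncoplanar_set, noncoplanar_set.drop("b0"))
        two = noncoplanar_set.subset(["b0", "b1"])
        with pytest.raises(ValueError, match="at least 3"):
            cm.fit_rigid(two, two)

    def test_collinear_source_raises_with_condition(self):
        line = cm.LandmarkSet(
            ("a", "b", "c", "d"),
            np.array([[0, 0, 0], [1, 0, 0], [2, 0, 0], [3.0, 0, 0]]),
        )
        with pytest.raises(DegenerateConfigurationError) as exc:
            cm.fit_rigid(line, line)
        assert exc.value.condition is not None
        assert exc.value.condition.degenerate


class TestErrorReport:
    def test_component_inequalities(self, rng, noncoplanar_set):
        dst = noncoplanar_set.with_points(
            noncoplanar_set.points + rng.normal(0, 0.2, (9, 3))
        )
        _, report = cm.fit_rigid(noncoplanar_set, dst)
        assert np.all(report.errors_3d >= report.planar_errors - 1e-12)
        assert np.all(
            report.planar_errors >= report.abs_xyz[:, :2].max(axis=1) - 1e-12
        )
        s = report.summary()
        assert s["min"] <= s["median"] <= s["max"]
        assert s["ci_lower"] <= s["mean"] <= s["ci_upper"]
        assert s["min"] <= s["mean"] <= s["max"]

    def test_per_landmark_table_keys(self, noncoplanar_set):
        _, report = cm.fit_rigid(noncoplanar_set, noncoplanar_set)
        table = report.per_landmark_table()
        assert set(table) == set(noncoplanar_set.labels)


class TestConditionNumber:
    def test_cube_closed_form(self):
        cube = np.array(
            [[x, y, z] for x in (-1, 1) for y in (-1, 1) for z in (-1, 1)],
            dtype=float,
        )
        report = cm.condition_number(
            cm.LandmarkSet(tuple(map(str, range(8))), cube)
        )
        expected_sigma = 2 * np.sqrt(2.0)
        assert np.allclose(report.singular_values, expected_sigma, atol=1e-12)
        assert report.condition_number == pytest.approx(100 / expected_sigma)
        assert report.sigma_ratio == pytest.approx(1.0)
        assert not report.degenerate

    def test_collinear_degenerate(self):
        line = np.outer(np.arange(4.0), [1.0, 1.0, 0.0])
        report = cm.condition_number(
            cm.LandmarkSet(tuple(map(str, range(4))), line)
        )
        assert report.singular_values[1] < 1e-12
        assert report.degenerate
        assert np.isinf(report.condition_number)

    def test_ring_planar_until_augmented(self, spec):
        ring = spec.prosthetic_landmarks()
        before = cm.condition_number(ring)
        assert before.singular_values[2] < 1e-12 and before.degenerate
        after = cm.condition_number(cm.augment_out_of_plane(ring))
        assert after.singular_values[2] > 1.0 and not after.degenerate


class TestAugmentOutOfPlane:
    def test_adds_exactly_one_synthetic_landmark(self, spec):
        ring = spec.prosthetic_landmarks()
        aug = cm.augment_out_of_plane(ring)
        assert len(aug) == len(ring) + 1
        assert aug.labels[:-1] == ring.labels
        assert aug.labels[-1] == OUT_OF_PLANE_LABEL

    def test_unit_triangle_lands_on_positive_z(self):
        tri = cm.LandmarkSet(
            ("a", "b", "c"),
            np.array([[0.0, 0, 0], [1.0, 0, 0], [0.0, 1, 0]]),
        )
        aug = cm.augment_out_of_plane(tri)
        added = aug.points[-1]
        # centroid + z_hat * mean centroid distance, by hand
        c = tri.points.mean(axis=0)
        s = np.linalg.norm(tri.points - c, axis=1).mean()
        assert np.allclose(added, [c[0], c[1], s], atol=1e-12)
        assert added[2] > 0

    def test_rigid_equivariance_leaves_fit_unchanged(self, rng, spec):
        ring = spec.prosthetic_landmarks()
        truth = random_rigid(rng, max_deg=15.0, max_t=10.0)
        moved = cm.apply(truth, ring)
        t_aug, _ = cm.fit_rigid(
            cm.augment_out_of_plane(ring), cm.augment_out_of_plane(moved)
        )
        assert np.allclose(t_aug.rotation, truth.rotation, atol=1e-9)
        assert np.allclose(t_aug.translation, truth.translation, atol=1e-9)

    def test_collinear_first_three_rejected(self):
        bad = cm.LandmarkSet(
            ("a", "b", "c", "d"),
            np.array([[0.0, 0, 0], [1.0, 0, 0], [2.0, 0, 0], [0.0, 1, 0]]),
        )
        with pytest.raises(DegenerateConfigurationError):
            cm.augment_out_of_plane(bad)

    def test_residuals_far_below_bead_spacing(self, rng, spec):
        # No landmark-interchange guard: residuals stay far below the
        # shortest inter-bead distance even under noise.
        pair, _ = cm.simulate_landmark_study(
            spec, random_rigid(rng), noise_sd=0.15, seed=5
        )
        result = cm.analyze_study(pair)
        pts = np.vstack([spec.bone_beads, spec.prosthetic_beads()])
        d = np.linalg.norm(pts[:, None] - pts[None], axis=-1)
        np.fill_diagonal(d, np.inf)
        assert result.bone_error.errors_3d.max() < d.min() / 10
        assert result.prosthetic_error.errors_3d.max() < d.min() / 10
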