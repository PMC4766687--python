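"""Least-squares rigid-body fitting of corresponding landmark sets.

The fit is the classical SVD solution of the orthogonal Procrustes problem
(Soederkvist-Wedin / Kabsch-Umeyama family): both point sets are centered on
their centroids, the cross-covariance is decomposed as U S V^T, and the
rotation is V diag(1, 1, det(V U^T)) U^T, the determinant correction
guarding against mirror inversion.  Residual statistics, configuration
condition numbers and the out-of-plane augmentation landmark used for
planar marker rings live here as well.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.stats

from .geometry import LandmarkSet, RigidTransform, centroid

__all__ = [
    "RegistrationErrorReport",
    "ConditionReport",
    "DegenerateConfigurationError",
    "fit_rigid",
    "condition_number",
    "augment_out_of_plane",
    "OUT_OF_PLANE_LABEL",
]

#: Label given to the synthetic landmark appended by augment_out_of_plane.
OUT_OF_PLANE_LABEL = "__out_of_plane__"

#: sigma3 < DEGENERACY_RTOL * sigma1 flags a configuration as degenerate.
DEGENERACY_RTOL = 1e-6


class DegenerateConfigurationError(ValueError):
    """Raised when a landmark configuration cannot support a rigid fit."""

    def __init__(self, message: str, condition: "ConditionReport | None" = None):
        super().__init__(message)
        self.condition = condition


@dataclass(frozen=True)
class ConditionReport:
    """Singular values of the centered 3xN landmark configuration.

    ``condition_number`` is 100 / sigma3 (the convention used in
    radiostereometric analysis, where large values flag marker
    configurations that ill-determine the fitted motion); the raw ratio
    sigma1 / sigma3 is reported alongside so either convention can be read
    off.  ``degenerate`` means sigma3 (or sigma2) vanishes relative to
    sigma1: the markers are coplanar/collinear.
    """

    singular_values: tuple
    condition_number: float
    sigma_ratio: float
    degenerate: bool

    @property
    def sigma1(self) -> float:
        return self.singular_values[0]

    @property
    def sigma3(self) -> float:
        return self.singular_values[2]


@dataclass(frozen=True)
class RegistrationErrorReport:
    """Per-landmark residual distances of a rigid fit, in mm.

    Residuals are reference minus transformed target.  Per landmark the
    report carries |dx|, |dy|, |dz|, the in-plane (x-y) error and the 3-D
    error; the summary describes the 3-D errors.
    """

    labels: tuple
    residuals: np.ndarray  # (N, 3) signed, reference - transformed target

    @property
    def abs_xyz(self) -> np.ndarray:
        return np.abs(self.residuals)

    @property
    def planar_errors(self) -> np.ndarray:
        return np.hypot(self.residuals[:, 0], self.residuals[:, 1])

    @property
    def errors_3d(self) -> np.ndarray:
        return np.linalg.norm(self.residuals, axis=1)

    @property
    def mean_error(self) -> float:
        """Mean 3-D residual: the 'mean error of rigid body fitting' (ME)."""
        return float(self.errors_3d.mean())

    def summary(self, confidence: float = 0.95) -> dict:
        e = self.errors_3d
        n = len(e)
        mean = float(e.mean())
        sd = float(e.std(ddof=1)) if n > 1 else 0.0
        if n > 1 and sd > 0:
            half = scipy.stats.t.ppf(0.5 + confidence / 2, n - 1) * sd / np.sqrt(n)
        else:
            half = 0.0
        return {
            "n": n,
            "mean": mean,
            "median": float(np.median(e)),
            "min": float(e.min()),
            "max": float(e.max()),
            "sd": sd,
            "ci_lower": mean - half,
            "ci_upper": mean + half,
        }

    def per_landmark_table(self) -> dict:
        """label -> dict of |dx|, |dy|, |dz|, planar, 3-D error (mm)."""
        out = {}
        for i, label in enumerate(self.labels):
            ax = self.abs_xyz[i]
            out[label] = {
                "abs_dx": float(ax[0]),
                "abs_dy": float(ax[1]),
                "abs_dz": float(ax[2]),
                "planar": float(self.planar_errors[i]),
                "error_3d": float(self.errors_3d[i]),
            }
        return out


def _centered(points: np.ndarray) -> np.ndarray:
    return points - points.mean(axis=0)


def condition_number(points: LandmarkSet | np.ndarray) -> ConditionReport:
    """Condition report of a marker configuration.

    Singular values of the 3xN matrix of centroid-centered coordinates;
    deterministic in the input order (singular values are order-invariant).
    """
    pts = points.points if isinstance(points, LandmarkSet) else np.atleast_2d(points)
    if pts.shape[0] < 3:
        raise ValueError(f"need at least 3 points, got {pts.shape[0]}")
    sv = np.linalg.svd(_centered(pts).T, compute_uv=False)
    s1, s2, s3 = (float(s) for s in sv)
    degenerate = s3 < DEGENERACY_RTOL * s1 or s1 == 0.0
    cond = 100.0 / s3 if s3 > 0 else np.inf
    ratio = s1 / s3 if s3 > 0 else np.inf
    return ConditionReport((s1, s2, s3), cond, ratio, degenerate)


def fit_rigid(
    source: LandmarkSet, destination: LandmarkSet
) -> tuple[RigidTransform, RegistrationErrorReport]:
    """Least-squares rigid transform mapping ``source`` onto ``destination``.

    Correspondence is by list order; both sets must have the same length
    (>= 3).  Returns the transform minimizing
    sum ||R s_i + t - d_i||^2 with det(R) = +1 enforced (a reflection in
    the unconstrained optimum is corrected by negating the last singular
    direction), together with the residual report d_i - (R s_i + t).

    Raises :class:`DegenerateConfigurationError` for collinear sources
    (sigma2 ~ 0), where the rotation about the line is unobservable.
    """
    if len(source) != len(destination):
        raise ValueError(
            f"landmark count mismatch: {len(source)} source vs "
            f"{len(destination)} destination"
        )
    if len(source) < 3:
        raise ValueError(f"need at least 3 corresponding points, got {len(source)}")

    s = source.points
    d = destination.points
    s0 = _centered(s)
    d0 = _centered(d)

    cond = condition_number(source)
    # Collinear: sigma2 ~ 0 leaves a rotation degree of freedom unobservable.
    if cond.singular_values[1] < DEGENERACY_RTOL * max(cond.sigma1, 1.0):
        raise DegenerateConfigurationError(
            "source landmarks are collinear (sigma2 ~ 0); rigid fit is "
            f"under-determined: {cond}",
            condition=cond,
        )

    h = d0.T @ s0  # cross-covariance, destination x source
    u, _, vt = np.linalg.svd(h)
    sign = np.sign(np.linalg.det(u @ vt))
    r = u @ np.diag([1.0, 1.0, sign]) @ vt
    t = d.mean(axis=0) - r @ s.mean(axis=0)

    transform = RigidTransform(r, t)
    residuals = d - transform.transform_points(s)
    report = RegistrationErrorReport(destination.labels, residuals)
    return transform, report


def augment_out_of_plane(points: LandmarkSet) -> LandmarkSet:
    """Append one synthetic out-of-plane landmark to a (near-)planar set.

    Planar marker rings (e.g. eight beads around a cup liner opening) give
    the rigid fit no purchase against mirror inversion; a point off the
    plane fixes the orientation.  The appended landmark sits at
    centroid + n_hat * s, where n_hat is the unit cross product
    (p2 - p1) x (p3 - p1) of the first three landmarks in list order and s
    is the mean distance of the landmarks from their centroid.  The
    construction is deterministic, scale-covariant and rigidly equivariant,
    so augmenting both sides of a rigidly related pair leaves the fitted
    transform unchanged.
    """
    if len(points) < 3:
        raise ValueError(f"need at least 3 points to augment, got {len(points)}")
    if points.has_label(OUT_OF_PLANE_LABEL):
        raise ValueError("landmark set already carries an out-of-plane landmark")
    p1, p2, p3 = points.points[:3]
    normal = np.cross(p2 - p1, p3 - p1)
    norm = np.linalg.norm(normal)
    extent = np.linalg.norm(points.points - points.points.mean(axis=0), axis=1).max()
    if norm <= 1e-12 * max(extent**2, 1.0):
        raise DegenerateConfigurationError(
            "first three landmarks are collinear; out-of-plane direction "
            "is undefined"
        )
    c = centroid(points)
    scale = float(np.linalg.norm(points.points - c, axis=1).mean())
    return points.append(OUT_OF_PLANE_LABEL, c + normal / norm * scale)
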