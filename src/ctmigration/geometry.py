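"""Core 3-D types and rigid-transform algebra.

World coordinates are right-handed LPS (+x left, +y posterior, +z superior,
the DICOM patient convention) in millimeters throughout the package.

Euler angles follow the clinical reporting convention used for implant
migration: a rotation is decomposed as a *clockwise* turn first about the
x axis, then y, then z, where "clockwise" means clockwise when looking
from the positive end of the axis toward the origin.  Algebraically the
composite matrix is

    R(rx, ry, rz) = Rz(-rz) @ Ry(-ry) @ Rx(-rx)

with ``Rx, Ry, Rz`` the standard right-handed (counter-clockwise)
rotation matrices and angles in degrees.  Any consistent sign convention
preserves rotation magnitudes, which are the clinically reported
quantities; this one is fixed so that numbers are reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, Sequence

import numpy as np

__all__ = [
    "EulerAnglesXYZ",
    "LandmarkSet",
    "RigidTransform",
    "as_point",
    "centroid",
    "rotation_from_euler",
    "euler_from_rotation",
    "require_rotation_matrix",
]

#: Roles a landmark set can play in a study.
ROLES = ("bone", "prosthetic", "anatomical")

_ORTHO_TOL = 1e-6  # construction-time sanity tolerance for rotation matrices


def as_point(p: Sequence[float]) -> np.ndarray:
    """Coerce ``p`` to a finite float (3,) array (world mm)."""
    a = np.asarray(p, dtype=float)
    if a.shape != (3,):
        raise ValueError(f"expected a 3-vector, got shape {a.shape}")
    if not np.all(np.isfinite(a)):
        raise ValueError(f"point has non-finite coordinates: {a}")
    return a


def require_rotation_matrix(r: np.ndarray, tol: float = _ORTHO_TOL) -> np.ndarray:
    """Validate that ``r`` is a proper rotation (orthonormal, det +1)."""
    r = np.asarray(r, dtype=float)
    if r.shape != (3, 3):
        raise ValueError(f"rotation matrix must be 3x3, got {r.shape}")
    if not np.allclose(r.T @ r, np.eye(3), atol=tol):
        raise ValueError("matrix is not orthonormal")
    if not np.isclose(np.linalg.det(r), 1.0, atol=tol):
        raise ValueError("matrix is not a proper rotation (det != +1)")
    return r


@dataclass(frozen=True)
class EulerAnglesXYZ:
    """Clockwise x-then-y-then-z Euler angles in degrees.

    ``gimbal_lock`` is set when the decomposition hit |ry| = 90 deg and the
    tie-break rx := 0 was applied (rz then absorbs the free angle).
    """

    rx: float
    ry: float
    rz: float
    gimbal_lock: bool = False

    def as_array(self) -> np.ndarray:
        return np.array([self.rx, self.ry, self.rz], dtype=float)


def _ccw_axis_matrix(axis: int, degrees: float) -> np.ndarray:
    c = np.cos(np.deg2rad(degrees))
    s = np.sin(np.deg2rad(degrees))
    m = np.eye(3)
    i, j = [(1, 2), (2, 0), (0, 1)][axis]
    m[i, i] = c
    m[j, j] = c
    m[i, j] = -s
    m[j, i] = s
    return m


def rotation_from_euler(angles: EulerAnglesXYZ | Sequence[float]) -> np.ndarray:
    """Rotation matrix for clockwise x-y-z Euler angles (degrees)."""
    if isinstance(angles, EulerAnglesXYZ):
        rx, ry, rz = angles.rx, angles.ry, angles.rz
    else:
        rx, ry, rz = (float(a) for a in angles)
    return (
        _ccw_axis_matrix(2, -rz) @ _ccw_axis_matrix(1, -ry) @ _ccw_axis_matrix(0, -rx)
    )


def euler_from_rotation(r: np.ndarray, gimbal_tol: float = 1e-7) -> EulerAnglesXYZ:
    """Decompose a rotation matrix into clockwise x-y-z Euler angles.

    Inverse of :func:`rotation_from_euler` away from gimbal lock.  At
    |ry| = 90 deg only rx - rz (or rx + rz) is determined; the documented
    tie-break fixes rx := 0 and flags the result.
    """
    r = require_rotation_matrix(r)
    # r = Rz(c) Ry(b) Rx(a) with a = -rx, b = -ry, c = -rz.
    sb = -r[2, 0]
    if abs(abs(sb) - 1.0) <= gimbal_tol:
        b = np.copysign(np.pi / 2, sb)
        a = 0.0
        c = np.arctan2(-r[0, 1], r[1, 1])
        lock = True
    else:
        b = np.arcsin(np.clip(sb, -1.0, 1.0))
        a = np.arctan2(r[2, 1], r[2, 2])
        c = np.arctan2(r[1, 0], r[0, 0])
        lock = False
    return EulerAnglesXYZ(
        rx=float(-np.rad2deg(a)),
        ry=float(-np.rad2deg(b)),
        rz=float(-np.rad2deg(c)),
        gimbal_lock=lock,
    )


@dataclass(frozen=True)
class RigidTransform:
    """Proper rigid motion p' = R @ p + t (rotation then translation, mm)."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "rotation", require_rotation_matrix(self.rotation).copy()
        )
        object.__setattr__(self, "translation", as_point(self.translation).copy())
        self.rotation.flags.writeable = False
        self.translation.flags.writeable = False

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    @classmethod
    def from_translation(cls, t: Sequence[float]) -> "RigidTransform":
        return cls(np.eye(3), t)

    @classmethod
    def from_euler(
        cls,
        angles: EulerAnglesXYZ | Sequence[float],
        translation: Sequence[float] = (0.0, 0.0, 0.0),
    ) -> "RigidTransform":
        return cls(rotation_from_euler(angles), translation)

    @classmethod
    def rotation_about_point(
        cls,
        angles: EulerAnglesXYZ | Sequence[float],
        center: Sequence[float],
        translation: Sequence[float] = (0.0, 0.0, 0.0),
    ) -> "RigidTransform":
        """Rotation about ``center`` plus an extra translation.

        p' = R (p - c) + c + t, the natural parameterization when motion is
        reported about a landmark-set centroid.
        """
        r = rotation_from_euler(angles)
        c = as_point(center)
        return cls(r, c - r @ c + as_point(translation))

    def transform_points(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        return pts @ self.rotation.T + self.translation

    def __call__(self, p: Sequence[float]) -> np.ndarray:
        return self.rotation @ as_point(p) + self.translation

    def inverse(self) -> "RigidTransform":
        rt = self.rotation.T
        return RigidTransform(rt, -rt @ self.translation)

    def euler_angles(self) -> EulerAnglesXYZ:
        return euler_from_rotation(self.rotation)

    def is_identity(self, tol: float = 1e-12) -> bool:
        return bool(
            np.allclose(self.rotation, np.eye(3), atol=tol)
            and np.allclose(self.translation, 0.0, atol=tol)
        )


def compose(a: RigidTransform, b: RigidTransform) -> RigidTransform:
    """Composite transform applying ``b`` first, then ``a``."""
    return RigidTransform(a.rotation @ b.rotation, a.rotation @ b.translation + a.translation)


@dataclass(frozen=True)
class LandmarkSet:
    """Ordered, labeled 3-D landmarks with a role.

    Order is significant: registration correspondence is by position in the
    list.  Labels are unique within a set.
    """

    labels: tuple
    points: np.ndarray
    role: str = "bone"

    def __post_init__(self) -> None:
        labels = tuple(str(l) for l in self.labels)
        pts = np.asarray(self.points, dtype=float)
        pts = np.atleast_2d(pts)
        if pts.ndim != 2 or pts.shape[1] != 3:
            raise ValueError(f"points must be (N, 3), got {pts.shape}")
        if len(labels) != pts.shape[0]:
            raise ValueError(
                f"{len(labels)} labels for {pts.shape[0]} points"
            )
        if len(set(labels)) != len(labels):
            dupes = sorted({l for l in labels if labels.count(l) > 1})
            raise ValueError(f"duplicate landmark labels: {dupes}")
        if not np.all(np.isfinite(pts)):
            raise ValueError("landmark coordinates must be finite")
        if self.role not in ROLES:
            raise ValueError(f"role must be one of {ROLES}, got {self.role!r}")
        object.__setattr__(self, "labels", labels)
        object.__setattr__(self, "points", pts.copy())
        self.points.flags.writeable = False

    def __len__(self) -> int:
        return len(self.labels)

    def __iter__(self) -> Iterator[tuple]:
        return iter(zip(self.labels, self.points))

    def point(self, label: str) -> np.ndarray:
        try:
            i = self.labels.index(label)
        except ValueError:
            raise KeyError(f"no landmark labeled {label!r}") from None
        return self.points[i]

    def has_label(self, label: str) -> bool:
        return label in self.labels

    def subset(self, labels: Iterable[str]) -> "LandmarkSet":
        labels = list(labels)
        idx = [self.labels.index(l) for l in labels]
        return LandmarkSet(tuple(labels), self.points[idx], self.role)

    def drop(self, label: str) -> "LandmarkSet":
        if label not in self.labels:
            raise KeyError(f"no landmark labeled {label!r}")
        keep = [l for l in self.labels if l != label]
        return self.subset(keep)

    def with_points(self, points: np.ndarray) -> "LandmarkSet":
        return LandmarkSet(self.labels, points, self.role)

    def append(self, label: str, point: Sequence[float]) -> "LandmarkSet":
        return LandmarkSet(
            self.labels + (str(label),),
            np.vstack([self.points, as_point(point)]),
            self.role,
        )


def apply(t: RigidTransform, points: LandmarkSet) -> LandmarkSet:
    """Map every landmark by p' = R p + t; labels, order and role preserved."""
    return points.with_points(t.transform_points(points.points))


def centroid(points: LandmarkSet | np.ndarray) -> np.ndarray:
    """Arithmetic mean of the landmark coordinates (the geometric weight point)."""
    pts = points.points if isinstance(points, LandmarkSet) else np.atleast_2d(points)
    if pts.shape[0] == 0:
        raise ValueError("centroid of an empty landmark set is undefined")
    return pts.mean(axis=0)
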