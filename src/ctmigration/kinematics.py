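"""Six-degree-of-freedom prosthetic motion from a paired CT study.

A study pairs a reference and a target examination of the same patient (or
phantom).  The analysis runs four fixed steps:

1. register the target to the reference by a rigid fit on the *bone*
   landmark sets (the pelvis defines the frame of reference);
2. carry the target prosthetic landmarks into the reference coordinate
   system with that bone transform;
3. rotate both prosthetic sets into a standard pelvic orientation (the
   McKibbin coronal plane through both anterior superior iliac spines and
   the pubic tubercles) when anatomical landmarks are available --
   otherwise the identity is applied;
4. fit the rigid transform that aligns the transferred target prosthetic
   set with the reference prosthetic set; its Euler angles and its
   translation expressed about the reference prosthetic centroid are the
   reported implant motion.

Because step 1 removes the whole-body repositioning between examinations,
the reported six degrees of freedom are invariant to how the patient lay in
the scanner -- the core guarantee of the method.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from . import registration
from .geometry import (
    LandmarkSet,
    RigidTransform,
    EulerAnglesXYZ,
    apply,
    centroid,
    euler_from_rotation,
)
from .registration import (
    ConditionReport,
    RegistrationErrorReport,
    OUT_OF_PLANE_LABEL,
    augment_out_of_plane,
    condition_number,
    fit_rigid,
)

__all__ = [
    "StudyPair",
    "MotionResult",
    "STUDY_TYPES",
    "ANATOMY_LABELS",
    "standard_orientation",
    "analyze_study",
    "translation_about_point",
]

STUDY_TYPES = ("double_examination", "interval", "provocation")

#: Anatomical labels defining the standard pelvic (McKibbin) orientation.
ANATOMY_LABELS = ("asis_left", "asis_right", "tubercle_left", "tubercle_right")

#: Prosthetic sets with sigma3/sigma1 below this are augmented automatically.
#: Loose enough that localization noise on an exactly planar marker ring
#: (which lifts sigma3 to the noise scale) still triggers the guard.
_PLANARITY_RTOL = 0.02


@dataclass(frozen=True)
class StudyPair:
    """Reference and target landmark sets of one paired-CT study."""

    reference_bone: LandmarkSet
    reference_prosthetic: LandmarkSet
    target_bone: LandmarkSet
    target_prosthetic: LandmarkSet
    anatomy: Optional[LandmarkSet] = None
    study_type: str = "double_examination"
    notes: str = ""

    def __post_init__(self) -> None:
        if self.study_type not in STUDY_TYPES:
            raise ValueError(
                f"study_type must be one of {STUDY_TYPES}, got {self.study_type!r}"
            )
        if self.reference_bone.labels != self.target_bone.labels:
            raise ValueError("bone landmark labels differ between reference and target")
        if self.reference_prosthetic.labels != self.target_prosthetic.labels:
            raise ValueError(
                "prosthetic landmark labels differ between reference and target"
            )
        overlap = set(self.reference_bone.labels) & set(
            self.reference_prosthetic.labels
        )
        if overlap:
            raise ValueError(f"bone and prosthetic labels overlap: {sorted(overlap)}")


@dataclass(frozen=True)
class MotionResult:
    """Prosthetic movement in six degrees of freedom plus the error report.

    Rotations are clockwise x-y-z Euler angles in degrees; translations in
    mm are expressed about the centroid of the reference prosthetic
    landmark set (the default rotation point), and additionally per
    landmark.  ``bone_error`` carries the registration residuals of step 1
    (its mean is the 'mean error of rigid body fitting'); ``prosthetic_error``
    the residuals of the final implant fit.
    """

    rotation: EulerAnglesXYZ
    translation_at_centroid: np.ndarray
    per_landmark_translations: dict
    rotation_point: np.ndarray
    bone_error: RegistrationErrorReport
    prosthetic_error: RegistrationErrorReport
    bone_condition: ConditionReport
    prosthetic_condition: ConditionReport
    standard_orientation_applied: bool
    implant_transform: RigidTransform
    bone_transform: RigidTransform

    def dof(self) -> np.ndarray:
        """(rx, ry, rz, tx, ty, tz) in degrees and mm."""
        return np.concatenate([self.rotation.as_array(), self.translation_at_centroid])


def translation_about_point(t: RigidTransform, rotation_point) -> np.ndarray:
    """Translation of ``t`` re-expressed about a rotation point c.

    Returns t' such that p -> R (p - c) + c + t' is the same map as t;
    algebraically t' = R c + t - c.  For a pure rotation about c itself
    this is zero: the reported translation is the motion *of* the rotation
    point.
    """
    c = np.asarray(rotation_point, dtype=float)
    return t.rotation @ c + t.translation - c


def _best_fit_plane_normal(points: np.ndarray) -> np.ndarray:
    """Unit normal of the total-least-squares plane (sign arbitrary)."""
    centered = points - points.mean(axis=0)
    _, s, vt = np.linalg.svd(centered)
    if points.shape[0] >= 3 and s[1] < 1e-9 * max(s[0], 1.0):
        raise registration.DegenerateConfigurationError(
            "anatomical landmarks are collinear; plane normal undefined"
        )
    return vt[2]


def standard_orientation(anatomy: LandmarkSet) -> np.ndarray:
    """Rotation into the standard pelvic (McKibbin) orientation.

    Requires at least three of the landmarks ``asis_left``, ``asis_right``,
    ``tubercle_left``, ``tubercle_right`` (non-collinear).  The standard
    frame is defined as: +x along the right-to-left direction (the
    inter-ASIS axis when both ASIS are present, else the inter-tubercle
    axis), +z along the best-fit plane normal oriented so that the
    ASIS-above-tubercle direction completes a right-handed frame, and
    y = z cross x.  Returns the pure rotation (3x3) that maps current world
    coordinates into that frame; for anatomy already in standard pose it is
    the identity, and pre-rotating the anatomy by Q returns Q^-1.
    """
    present = [l for l in ANATOMY_LABELS if anatomy.has_label(l)]
    if len(present) < 3:
        raise ValueError(
            f"standard orientation needs >= 3 of {ANATOMY_LABELS}, "
            f"found {present}"
        )
    pts = {l: anatomy.point(l) for l in present}

    if "asis_left" in pts and "asis_right" in pts:
        x_raw = pts["asis_left"] - pts["asis_right"]
    else:
        x_raw = pts["tubercle_left"] - pts["tubercle_right"]
    nx = np.linalg.norm(x_raw)
    if nx < 1e-12:
        raise ValueError("left and right landmarks coincide")
    x_hat = x_raw / nx

    asis = [pts[l] for l in ("asis_left", "asis_right") if l in pts]
    tubercles = [pts[l] for l in ("tubercle_left", "tubercle_right") if l in pts]
    up_raw = np.mean(asis, axis=0) - np.mean(tubercles, axis=0)

    normal = _best_fit_plane_normal(np.array([pts[l] for l in present]))
    # Orient the normal so (x, up, normal) is right-handed.
    if np.dot(np.cross(x_hat, up_raw), normal) < 0:
        normal = -normal
    # Orthogonalize against x (noisy landmarks need not be exactly planar).
    z_raw = normal - (normal @ x_hat) * x_hat
    nz = np.linalg.norm(z_raw)
    if nz < 1e-12:
        raise ValueError("plane normal is parallel to the left-right axis")
    z_hat = z_raw / nz
    y_hat = np.cross(z_hat, x_hat)
    return np.vstack([x_hat, y_hat, z_hat])


def _maybe_augment(ref: LandmarkSet, tgt: LandmarkSet, mode) -> tuple:
    """Augment both sets with the out-of-plane landmark when (near-)planar.

    The same first-three-landmark rule is used on both sides so the added
    points correspond.
    """
    if mode is False:
        return ref, tgt
    if mode is True:
        return augment_out_of_plane(ref), augment_out_of_plane(tgt)
    # mode == "auto": augment when either configuration is nearly planar,
    # as a marker ring around a cup opening always is.
    def near_planar(s: LandmarkSet) -> bool:
        sv = condition_number(s).singular_values
        return sv[2] < _PLANARITY_RTOL * max(sv[0], 1e-12)

    if near_planar(ref) or near_planar(tgt):
        return augment_out_of_plane(ref), augment_out_of_plane(tgt)
    return ref, tgt


def analyze_study(pair: StudyPair, augment="auto") -> MotionResult:
    """Run the four-step analysis on a study pair.

    ``augment`` controls the out-of-plane landmark for the prosthetic sets:
    "auto" (default) appends it when the configuration is near-planar,
    True/False force it.  The synthetic landmark participates in the fits
    but is excluded from per-landmark outputs and from the rotation-point
    centroid.
    """
    # Step 1: bone registration, target -> reference.
    t_bone, bone_error = fit_rigid(pair.target_bone, pair.reference_bone)

    # Step 2: transfer target prosthetic landmarks into the reference frame.
    prosthetic_target = apply(t_bone, pair.target_prosthetic)

    # Step 3: standard pelvic orientation (identity when anatomy is absent).
    if pair.anatomy is not None:
        s_matrix = standard_orientation(pair.anatomy)
        oriented = True
    else:
        s_matrix = np.eye(3)
        oriented = False
    s_transform = RigidTransform(s_matrix, np.zeros(3))
    ref_prosthetic = apply(s_transform, pair.reference_prosthetic)
    tgt_prosthetic = apply(s_transform, prosthetic_target)

    # Step 4: implant fit about the reference prosthetic centroid.
    ref_aug, tgt_aug = _maybe_augment(ref_prosthetic, tgt_prosthetic, augment)
    t_impl, prosthetic_error = fit_rigid(tgt_aug, ref_aug)

    rotation_point = centroid(ref_prosthetic)  # original landmarks only
    t_centroid = translation_about_point(t_impl, rotation_point)

    per_landmark = {
        label: t_impl(point) - point
        for label, point in ref_prosthetic
    }

    bone_condition = condition_number(pair.reference_bone)
    prosthetic_condition = condition_number(ref_aug)

    return MotionResult(
        rotation=euler_from_rotation(t_impl.rotation),
        translation_at_centroid=t_centroid,
        per_landmark_translations=per_landmark,
        rotation_point=rotation_point,
        bone_error=bone_error,
        prosthetic_error=prosthetic_error,
        bone_condition=bone_condition,
        prosthetic_condition=prosthetic_condition,
        standard_orientation_applied=oriented,
        implant_transform=t_impl,
        bone_transform=t_bone,
    )
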