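"""File formats: landmark CSV/FCSV, CT volumes, study definitions, reports.

In-memory coordinates are always LPS millimeters; every dialect conversion
(e.g. the RAS convention of Slicer fiducial markup files) happens here at
the I/O boundary and nowhere else.  A landmark file without an explicit,
recognized coordinate-frame tag is an error -- coordinates are never
silently reinterpreted.
"""

from __future__ import annotations

import csv
import json
import os
from pathlib import Path
from typing import Optional

import numpy as np
import SimpleITK as sitk

from . import __version__
from .bead_localization import VoxelVolume
from .geometry import LandmarkSet
from .kinematics import MotionResult, StudyPair

__all__ = [
    "read_landmarks",
    "write_landmarks",
    "read_volume",
    "write_volume",
    "load_study",
    "motion_result_to_dict",
    "write_report",
    "LandmarkFileError",
]

_FRAMES = ("LPS", "RAS")


class LandmarkFileError(ValueError):
    """Malformed landmark file; carries the offending line number when known."""


def _ras_to_lps(points: np.ndarray) -> np.ndarray:
    out = points.copy()
    out[:, 0] *= -1
    out[:, 1] *= -1
    return out


def write_landmarks(path, landmarks: LandmarkSet, dialect: str = "csv") -> None:
    """Write a landmark set; ``dialect`` is 'csv' (LPS) or 'fcsv' (RAS)."""
    path = Path(path)
    if dialect == "csv":
        with open(path, "w", newline="") as fh:
            fh.write("# ctmigration landmarks\n")
            fh.write("# frame: LPS\n")
            fh.write("# units: mm\n")
            writer = csv.writer(fh)
            writer.writerow(["label", "x", "y", "z", "role", "note"])
            for label, p in landmarks:
                writer.writerow(
                    [label, repr(float(p[0])), repr(float(p[1])),
                     repr(float(p[2])), landmarks.role, ""]
                )
    elif dialect == "fcsv":
        pts = _ras_to_lps(landmarks.points)  # LPS -> RAS is the same flip
        with open(path, "w", newline="") as fh:
            fh.write("# Markups fiducial file version = 4.11\n")
            fh.write("# CoordinateSystem = RAS\n")
            fh.write(
                "# columns = id,x,y,z,ow,ox,oy,oz,vis,sel,lock,label,desc,"
                "associatedNodeID\n"
            )
            for i, (label, _) in enumerate(landmarks):
                x, y, z = (repr(float(v)) for v in pts[i])
                fh.write(
                    f"vtkMRMLMarkupsFiducialNode_{i},{x},{y},{z},"
                    f"0,0,0,1,1,1,0,{label},,\n"
                )
    else:
        raise ValueError(f"unknown landmark dialect {dialect!r}")


def read_landmarks(
    path, dialect: Optional[str] = None, role: str = "bone"
) -> LandmarkSet:
    """Read a landmark set, converting file coordinates to LPS mm.

    ``dialect`` is inferred from the extension when omitted ('.fcsv' vs
    '.csv').  The CSV dialect carries its own role column; ``role`` is used
    for FCSV files (which have none).
    """
    path = Path(path)
    if dialect is None:
        dialect = "fcsv" if path.suffix.lower() == ".fcsv" else "csv"
    if dialect == "csv":
        return _read_csv(path)
    if dialect == "fcsv":
        return _read_fcsv(path, role)
    raise ValueError(f"unknown landmark dialect {dialect!r}")


def _read_csv(path: Path) -> LandmarkSet:
    frame = None
    labels, points, roles = [], [], []
    with open(path, newline="") as fh:
        rows = list(fh)
    data_rows = []
    for lineno, line in enumerate(rows, start=1):
        stripped = line.strip()
        if not stripped:
            continue
        if stripped.startswith("#"):
            body = stripped.lstrip("#").strip()
            if body.lower().startswith("frame:"):
                frame = body.split(":", 1)[1].strip().upper()
            continue
        data_rows.append((lineno, stripped))
    if frame is None:
        raise LandmarkFileError(
            f"{path}: missing '# frame:' header; refusing to guess the "
            "coordinate frame"
        )
    if frame not in _FRAMES:
        raise LandmarkFileError(
            f"{path}: unknown coordinate frame {frame!r} (expected one of "
            f"{_FRAMES})"
        )
    if not data_rows:
        raise LandmarkFileError(f"{path}: no landmark rows")
    header_line, first = data_rows[0]
    reader = csv.reader([row for _, row in data_rows])
    header = next(reader)
    expected = ["label", "x", "y", "z", "role"]
    if [h.strip().lower() for h in header[:5]] != expected:
        raise LandmarkFileError(
            f"{path}:{header_line}: expected columns {expected}, got {header}"
        )
    for (lineno, _), row in zip(data_rows[1:], reader):
        if len(row) < 5:
            raise LandmarkFileError(
                f"{path}:{lineno}: expected >= 5 fields, got {len(row)}"
            )
        try:
            points.append([float(row[1]), float(row[2]), float(row[3])])
        except ValueError as exc:
            raise LandmarkFileError(f"{path}:{lineno}: {exc}") from None
        labels.append(row[0].strip())
        roles.append(row[4].strip())
    if len(set(roles)) > 1:
        raise LandmarkFileError(
            f"{path}: mixed roles {sorted(set(roles))} in one landmark set"
        )
    pts = np.asarray(points)
    if frame == "RAS":
        pts = _ras_to_lps(pts)
    try:
        return LandmarkSet(tuple(labels), pts, roles[0])
    except ValueError as exc:
        raise LandmarkFileError(f"{path}: {exc}") from None


def _read_fcsv(path: Path, role: str) -> LandmarkSet:
    frame = None
    labels, points = [], []
    with open(path, newline="") as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped:
                continue
            if stripped.startswith("#"):
                body = stripped.lstrip("#").strip()
                if body.lower().startswith("coordinatesystem"):
                    tag = body.split("=", 1)[1].strip().upper()
                    frame = {"0": "RAS", "1": "LPS"}.get(tag, tag)
                continue
            fields = stripped.split(",")
            if len(fields) < 12:
                raise LandmarkFileError(
                    f"{path}:{lineno}: expected >= 12 comma-separated fields, "
                    f"got {len(fields)}"
                )
            try:
                points.append([float(fields[1]), float(fields[2]), float(fields[3])])
            except ValueError as exc:
                raise LandmarkFileError(f"{path}:{lineno}: {exc}") from None
            labels.append(fields[11].strip())
    if frame is None:
        raise LandmarkFileError(
            f"{path}: missing '# CoordinateSystem' header; refusing to guess"
        )
    if frame not in _FRAMES:
        raise LandmarkFileError(f"{path}: unknown coordinate system {frame!r}")
    pts = np.asarray(points, dtype=float)
    if pts.size == 0:
        raise LandmarkFileError(f"{path}: no landmark rows")
    if frame == "RAS":
        pts = _ras_to_lps(pts)
    try:
        return LandmarkSet(tuple(labels), pts, role)
    except ValueError as exc:
        raise LandmarkFileError(f"{path}: {exc}") from None


def _check_metaimage_spacing(path: Path) -> None:
    """MetaImage headers may omit ElementSpacing; never assume 1 mm."""
    header_path = path
    with open(header_path, "rb") as fh:
        header = fh.read(8192).decode("latin-1", errors="replace")
    keys = {
        line.split("=", 1)[0].strip()
        for line in header.splitlines()
        if "=" in line
    }
    if "ElementSpacing" not in keys and "ElementSize" not in keys:
        raise ValueError(
            f"{path}: MetaImage header lacks ElementSpacing/ElementSize; "
            "voxel spacing is unknown (will not assume 1 mm)"
        )


def read_volume(path) -> VoxelVolume:
    """Read a CT volume (NIfTI, MetaImage, or a DICOM series directory).

    The world mapping (spacing, origin, direction) is returned in LPS mm,
    the native frame of the underlying toolkit; NIfTI's RAS header
    convention is converted internally by the reader.
    """
    path = Path(path)
    if path.is_dir():
        reader = sitk.ImageSeriesReader()
        files = reader.GetGDCMSeriesFileNames(str(path))
        if not files:
            raise ValueError(f"{path}: no DICOM series found")
        reader.SetFileNames(files)
        image = reader.Execute()
    else:
        if not path.exists():
            raise FileNotFoundError(path)
        if path.suffix.lower() in (".mhd", ".mha"):
            _check_metaimage_spacing(path)
        elif path.suffix.lower() not in (".nii", ".gz"):
            raise ValueError(
                f"{path}: unsupported volume format {path.suffix!r} "
                "(expected .nii, .nii.gz, .mha, .mhd or a DICOM directory)"
            )
        image = sitk.ReadImage(str(path))
    array = sitk.GetArrayFromImage(image).astype(float)  # [z, y, x]
    data = np.transpose(array, (2, 1, 0))
    direction = np.asarray(image.GetDirection(), dtype=float).reshape(3, 3)
    return VoxelVolume(
        data,
        np.asarray(image.GetSpacing(), dtype=float),
        np.asarray(image.GetOrigin(), dtype=float),
        direction,
    )


def write_volume(path, volume: VoxelVolume) -> None:
    """Write a volume as NIfTI or MetaImage (by extension)."""
    path = Path(path)
    image = sitk.GetImageFromArray(np.transpose(volume.data, (2, 1, 0)))
    image.SetSpacing(tuple(volume.spacing))
    image.SetOrigin(tuple(volume.origin))
    image.SetDirection(tuple(volume.direction.ravel()))
    sitk.WriteImage(image, str(path))


def load_study(path) -> StudyPair:
    """Load a study definition JSON into a StudyPair.

    The definition names landmark files for the reference and target
    examinations (paths relative to the JSON file)::

        {
          "study_type": "double_examination",
          "reference": {"bone": "...", "prosthetic": "...", "anatomy": "..."},
          "target": {"bone": "...", "prosthetic": "..."}
        }
    """
    path = Path(path)
    with open(path) as fh:
        spec = json.load(fh)
    base = path.parent

    def lm(section: str, key: str, role: str, required: bool = True):
        entry = spec.get(section, {}).get(key)
        if entry is None:
            if required:
                raise ValueError(f"{path}: missing {section}.{key}")
            return None
        return read_landmarks(base / entry, role=role)

    return StudyPair(
        reference_bone=lm("reference", "bone", "bone"),
        reference_prosthetic=lm("reference", "prosthetic", "prosthetic"),
        target_bone=lm("target", "bone", "bone"),
        target_prosthetic=lm("target", "prosthetic", "prosthetic"),
        anatomy=lm("reference", "anatomy", "anatomical", required=False),
        study_type=spec.get("study_type", "double_examination"),
        notes=spec.get("notes", ""),
    )


def motion_result_to_dict(
    result: MotionResult, provenance: Optional[dict] = None
) -> dict:
    """Serialize a MotionResult (full precision; rounding is display-only)."""
    out = {
        "rotation_deg": {
            "rx": result.rotation.rx,
            "ry": result.rotation.ry,
            "rz": result.rotation.rz,
            "gimbal_lock": result.rotation.gimbal_lock,
        },
        "translation_mm": {
            "tx": float(result.translation_at_centroid[0]),
            "ty": float(result.translation_at_centroid[1]),
            "tz": float(result.translation_at_centroid[2]),
        },
        "rotation_point_mm": [float(v) for v in result.rotation_point],
        "per_landmark_translations_mm": {
            k: [float(x) for x in v]
            for k, v in result.per_landmark_translations.items()
        },
        "mean_registration_error_bone_mm": result.bone_error.mean_error,
        "mean_registration_error_prosthesis_mm": result.prosthetic_error.mean_error,
        "bone_error": result.bone_error.summary(),
        "prosthetic_error": result.prosthetic_error.summary(),
        "bone_condition": {
            "singular_values": list(result.bone_condition.singular_values),
            "condition_number": result.bone_condition.condition_number,
            "degenerate": result.bone_condition.degenerate,
        },
        "prosthetic_condition": {
            "singular_values": list(result.prosthetic_condition.singular_values),
            "condition_number": result.prosthetic_condition.condition_number,
            "degenerate": result.prosthetic_condition.degenerate,
        },
        "standard_orientation_applied": result.standard_orientation_applied,
    }
    prov = {"software_version": __version__}
    if provenance:
        prov.update(provenance)
    out["provenance"] = prov
    return out


def write_report(path, result: MotionResult, provenance: Optional[dict] = None) -> None:
    with open(path, "w") as fh:
        json.dump(motion_result_to_dict(result, provenance), fh, indent=2)
        fh.write("\n")
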