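"""Sub-voxel localization of tantalum beads and spheres in CT volumes.

A 1-mm tantalum bead spans only a couple of voxels at clinical CT
resolution (0.7-mm pixels, 0.5-mm slices), so its apparent shape is
dominated by the partial-volume effect: boundary voxels carry an
attenuation proportional to the fraction of the voxel inside the bead.
The center estimator here exploits exactly that: it selects the
supra-threshold connected component nearest an operator seed, extends it
by one voxel to recapture the partial-volume shell, and takes the
background-subtracted intensity-weighted centroid, which localizes the
bead well below the voxel size.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.ndimage

from .geometry import as_point

__all__ = [
    "VoxelVolume",
    "BeadDetection",
    "BeadNotFoundError",
    "refine_bead_center",
    "detect_all_beads",
    "fit_sphere",
]

_STRUCTURE_26 = np.ones((3, 3, 3), dtype=bool)


class BeadNotFoundError(ValueError):
    """No supra-threshold component within reach of the seed."""


@dataclass(frozen=True)
class VoxelVolume:
    """3-D scalar grid with a millimeter world mapping.

    ``data`` is indexed ``[i, j, k]`` along the volume's x, y, z axes;
    voxel index ``v`` maps to world coordinates (LPS mm) as
    ``origin + direction @ (spacing * v)``.  ``origin`` is the world
    position of voxel (0, 0, 0); ``direction`` is the orthonormal
    voxel-to-world axis matrix (columns are the world directions of the
    index axes).
    """

    data: np.ndarray
    spacing: np.ndarray
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))
    direction: np.ndarray = field(default_factory=lambda: np.eye(3))

    def __post_init__(self) -> None:
        data = np.asarray(self.data, dtype=float)
        if data.ndim != 3:
            raise ValueError(f"volume data must be 3-D, got ndim={data.ndim}")
        spacing = as_point(self.spacing)
        if np.any(spacing <= 0):
            raise ValueError(f"voxel spacing must be positive, got {spacing}")
        direction = np.asarray(self.direction, dtype=float)
        if direction.shape != (3, 3) or not np.isclose(
            abs(np.linalg.det(direction)), 1.0, atol=1e-6
        ):
            raise ValueError("direction must be a 3x3 orthonormal axis matrix")
        object.__setattr__(self, "data", data)
        object.__setattr__(self, "spacing", spacing)
        object.__setattr__(self, "origin", as_point(self.origin))
        object.__setattr__(self, "direction", direction)

    @property
    def shape(self) -> tuple:
        return self.data.shape

    def index_to_world(self, indices: np.ndarray) -> np.ndarray:
        idx = np.atleast_2d(np.asarray(indices, dtype=float))
        return (idx * self.spacing) @ self.direction.T + self.origin

    def world_to_index(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        return ((pts - self.origin) @ self.direction) / self.spacing

    def contains(self, point) -> bool:
        idx = self.world_to_index(as_point(point))[0]
        return bool(np.all(idx >= -0.5) and np.all(idx <= np.array(self.shape) - 0.5))

    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))


@dataclass(frozen=True)
class BeadDetection:
    """One localized bead: sub-voxel center (world mm) plus quality data."""

    center: np.ndarray
    radius: float
    n_voxels: int
    touching_boundary: bool = False
    merged_with_neighbor: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(self, "center", as_point(self.center))
        if self.n_voxels < 1:
            raise ValueError("a detection needs at least one supporting voxel")
        if self.radius <= 0:
            raise ValueError("fitted radius must be positive")


def _component_center(
    volume: VoxelVolume,
    mask: np.ndarray,
    offset: np.ndarray,
    threshold: float,
    weighting: str,
) -> tuple[np.ndarray, float, int]:
    """Center (world mm), equivalent radius and voxel count of one component.

    ``weighting='intensity'`` dilates the mask by one voxel (26-neighborhood)
    and weights by background-subtracted intensity, recovering the
    partial-volume shell; ``'binary'`` is the plain geometric centroid of the
    supra-threshold mask, kept for sensitivity analyses.
    """
    n_voxels = int(mask.sum())
    sub = volume.data[
        offset[0] : offset[0] + mask.shape[0],
        offset[1] : offset[1] + mask.shape[1],
        offset[2] : offset[2] + mask.shape[2],
    ]
    if weighting == "intensity":
        support = scipy.ndimage.binary_dilation(mask, structure=_STRUCTURE_26)
        below = sub[~support]
        background = float(np.median(below)) if below.size else 0.0
        weights = np.where(support, np.clip(sub - background, 0.0, None), 0.0)
    elif weighting == "binary":
        weights = mask.astype(float)
    else:
        raise ValueError(f"unknown weighting {weighting!r}")
    total = weights.sum()
    if total <= 0:
        weights = mask.astype(float)
        total = weights.sum()
    idx = np.indices(mask.shape, dtype=float)
    local = np.array([float((idx[a] * weights).sum() / total) for a in range(3)])
    center = volume.index_to_world(local + offset)[0]
    eq_radius = (3.0 * n_voxels * volume.voxel_volume_mm3() / (4.0 * np.pi)) ** (1 / 3)
    return center, eq_radius, n_voxels


def refine_bead_center(
    volume: VoxelVolume,
    seed,
    threshold: float,
    max_radius: float = 2.0,
    weighting: str = "intensity",
) -> BeadDetection:
    """Refine an approximate (operator-seeded) bead position to sub-voxel.

    Selects the 26-connected supra-threshold component nearest ``seed``
    within ``max_radius`` (mm; default twice a 1-mm bead diameter, bounding
    the search around the seed) and returns its weighted-centroid center.
    Deterministic.  A component reaching the search-ball boundary is
    flagged ``touching_boundary`` (it may continue into a neighboring
    structure such as the cup shell); a component whose spatial extent is
    far larger than its equivalent radius is flagged
    ``merged_with_neighbor``.
    """
    seed = as_point(seed)
    if not volume.contains(seed):
        raise ValueError(f"seed {seed} lies outside the volume")

    # Crop to the bounding box of the search ball.
    seed_idx = volume.world_to_index(seed)[0]
    pad = max_radius / volume.spacing
    lo = np.maximum(np.floor(seed_idx - pad).astype(int), 0)
    hi = np.minimum(np.ceil(seed_idx + pad).astype(int) + 1, volume.shape)
    crop = volume.data[lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]]
    mask = crop > threshold
    if not mask.any():
        raise BeadNotFoundError(
            f"no voxel above threshold {threshold} within {max_radius} mm of seed"
        )
    labels, n_comp = scipy.ndimage.label(mask, structure=_STRUCTURE_26)

    idx = np.indices(crop.shape, dtype=float)
    world = volume.index_to_world(
        np.stack([idx[a] for a in range(3)], axis=-1).reshape(-1, 3) + lo
    ).reshape(crop.shape + (3,))
    dist = np.linalg.norm(world - seed, axis=-1)

    best_label, best_dist = 0, np.inf
    for comp in range(1, n_comp + 1):
        d = dist[labels == comp].min()
        if d < best_dist:
            best_label, best_dist = comp, d
    if best_dist > max_radius:
        raise BeadNotFoundError(
            f"nearest supra-threshold component is {best_dist:.2f} mm from the "
            f"seed, beyond max_radius={max_radius} mm"
        )

    comp_mask = labels == best_label
    # Only keep the component's voxels inside the search ball; note if it
    # continues past the boundary.
    in_ball = dist <= max_radius
    touching = bool((comp_mask & ~in_ball).any())
    comp_mask = comp_mask & in_ball

    center, eq_radius, n_voxels = _component_center(
        volume, comp_mask, lo, threshold, weighting
    )
    extent = dist[comp_mask].max() - best_dist
    merged = bool(extent > 3.0 * eq_radius + max(volume.spacing))
    return BeadDetection(center, eq_radius, n_voxels, touching, merged)


def detect_all_beads(
    volume: VoxelVolume,
    threshold: float,
    diameter_range: tuple = (0.5, 2.0),
    weighting: str = "intensity",
) -> list:
    """Detect every bead-sized supra-threshold blob in the volume.

    Batch companion of :func:`refine_bead_center` for synthetic phantoms and
    automation: all 26-connected supra-threshold components whose equivalent
    diameter (from voxel count) lies in ``diameter_range`` (mm) are
    localized and returned sorted by center (z, then y, then x).  An empty
    list is a valid result.
    """
    lo_d, hi_d = diameter_range
    mask = volume.data > threshold
    if not mask.any():
        return []
    labels, n_comp = scipy.ndimage.label(mask, structure=_STRUCTURE_26)
    detections = []
    slices = scipy.ndimage.find_objects(labels)
    for comp, slc in enumerate(slices, start=1):
        if slc is None:
            continue
        # Expand the tight bounding box so the dilated partial-volume shell
        # stays inside the crop.
        grown = tuple(
            slice(max(s.start - 2, 0), min(s.stop + 2, dim))
            for s, dim in zip(slc, volume.shape)
        )
        offset = np.array([s.start for s in grown])
        comp_mask = labels[grown] == comp
        n_voxels = int(comp_mask.sum())
        eq_d = 2.0 * (
            3.0 * n_voxels * volume.voxel_volume_mm3() / (4.0 * np.pi)
        ) ** (1 / 3)
        if not (lo_d <= eq_d <= hi_d):
            continue
        center, eq_radius, n_voxels = _component_center(
            volume, comp_mask, offset, threshold, weighting
        )
        edge = any(
            s.start == 0 or s.stop == dim for s, dim in zip(slc, volume.shape)
        )
        detections.append(
            BeadDetection(center, eq_radius, n_voxels, touching_boundary=edge)
        )
    detections.sort(key=lambda d: (d.center[2], d.center[1], d.center[0]))
    return detections


def fit_sphere(points) -> tuple[np.ndarray, float, float]:
    """Least-squares sphere through >= 4 points.

    Algebraic (Coope) linearization -- solve ||p||^2 = 2 c.p + (r^2 - ||c||^2)
    by linear least squares -- refined by one geometric Gauss-Newton pass on
    sum (||p_i - c|| - r)^2.  Returns (center, radius, rms_residual) where
    the residual is RMS of ||p_i - c|| - r in mm.  Used for the femoral-head
    sphere landmark and for reconstructing a missing extraction-hole marker
    from points on the hole rim.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    if pts.shape[0] < 4 or pts.shape[1] != 3:
        raise ValueError(
            f"sphere fit needs at least 4 points of dimension 3, got {pts.shape}"
        )
    a = np.hstack([2.0 * pts, np.ones((pts.shape[0], 1))])
    b = (pts**2).sum(axis=1)
    sol, _, rank, _ = np.linalg.lstsq(a, b, rcond=None)
    if rank < 4:
        raise ValueError(
            "degenerate point configuration (coplanar/cocircular): sphere "
            "fit is singular"
        )
    center = sol[:3]
    r2 = sol[3] + center @ center
    if r2 <= 0:
        raise ValueError("sphere fit produced a non-positive radius")
    radius = float(np.sqrt(r2))

    # One Gauss-Newton step on the geometric distance residual.
    diff = pts - center
    dist = np.linalg.norm(diff, axis=1)
    if np.all(dist > 0):
        jac = np.hstack([-diff / dist[:, None], -np.ones((pts.shape[0], 1))])
        res = dist - radius
        step, *_ = np.linalg.lstsq(jac, -res, rcond=None)
        center = center + step[:3]
        radius = float(radius + step[3])
        dist = np.linalg.norm(pts - center, axis=1)

    rms = float(np.sqrt(np.mean((dist - radius) ** 2)))
    return center, radius, rms
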