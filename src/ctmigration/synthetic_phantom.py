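"""Synthetic pelvic-phantom studies with known ground truth.

The generator emulates the validation design used for marker-based
migration measurement: a pelvis phantom carrying nine bone beads in the
periacetabular region and eight prosthetic beads in a ring around the cup
liner opening (1-mm tantalum spheres), scanned repeatedly in arbitrary
whole-body positions.  Pairing repositioned examinations yields studies
whose true implant motion is exactly zero (the null design); a known
implant motion can be injected on top for parameter-recovery experiments.

Two levels of synthesis are provided:

* landmark level -- bead *positions* with i.i.d. isotropic Gaussian
  localization noise, the fast path for statistical experiments;
* voxel level -- beads rasterized into a CT-like grid (0.72-mm pixels,
  0.5-mm slices by default) with analytic partial-volume weighting, the
  path that exercises sub-voxel bead localization.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .bead_localization import VoxelVolume
from .geometry import LandmarkSet, RigidTransform, as_point, compose
from .kinematics import StudyPair

__all__ = [
    "PhantomSpec",
    "GroundTruth",
    "antithetic_noise_pair",
    "simulate_landmark_study",
    "simulate_model_experiment",
    "simulate_repeated_trials",
    "random_repositioning",
    "implant_motion_about_centroid",
    "rasterize_phantom",
]

# Fixed default bead geometry (mm, cup-opening center at the origin).
# Nine bone beads spread over a periacetabular-like shell, pairwise
# separations well above 8 mm and clearly non-coplanar.
_DEFAULT_BONE_BEADS = np.array(
    [
        [40.0, 10.0, 18.0],
        [30.0, -25.0, 25.0],
        [-35.0, 20.0, 22.0],
        [-28.0, -30.0, 20.0],
        [10.0, 38.0, 30.0],
        [-5.0, -40.0, 28.0],
        [22.0, 5.0, 45.0],
        [-18.0, -8.0, 42.0],
        [3.0, 18.0, 55.0],
    ]
)

# Anatomical landmarks of the McKibbin (coronal) plane, laid out in the
# standard reporting pose: inter-ASIS axis along +x, plane normal along +z.
_DEFAULT_ANATOMY = {
    "asis_left": np.array([120.0, 80.0, 0.0]),
    "asis_right": np.array([-120.0, 80.0, 0.0]),
    "tubercle_left": np.array([40.0, 0.0, 0.0]),
    "tubercle_right": np.array([-40.0, 0.0, 0.0]),
}


def _ring_points(n: int, diameter: float) -> np.ndarray:
    """n beads equally spaced on a circle in the z = 0 plane."""
    angles = 2 * np.pi * np.arange(n) / n
    r = diameter / 2.0
    return np.column_stack(
        [r * np.cos(angles), r * np.sin(angles), np.zeros(n)]
    )


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry and imaging parameters of the synthetic phantom.

    Distances in mm, intensities in HU-like units.  The default prosthetic
    ring is 8 beads on a 54-mm circle (cup-opening scale) in the z = 0
    plane -- exactly planar, so the analysis must augment it with an
    out-of-plane landmark.  ``deformed_bead`` names a prosthetic bead to
    render elongated (a partial-volume / beam-hardening artifact stand-in)
    by factor ``deformity_elongation`` along the radial direction.
    """

    bone_beads: np.ndarray = field(
        default_factory=lambda: _DEFAULT_BONE_BEADS.copy()
    )
    ring_n_beads: int = 8
    ring_diameter: float = 54.0
    bead_diameter: float = 1.0
    head_diameter: float = 28.0
    head_center: np.ndarray = field(
        default_factory=lambda: np.array([0.0, 0.0, -12.0])
    )
    include_cup_shell: bool = False
    cup_shell_radius: float = 29.0
    cup_shell_thickness: float = 2.0
    voxel_spacing: tuple = (0.72, 0.72, 0.5)
    background_intensity: float = 0.0
    metal_intensity: float = 3000.0
    noise_sd_hu: float = 0.0
    deformed_bead: Optional[str] = None
    deformity_elongation: float = 2.0

    def __post_init__(self) -> None:
        beads = np.atleast_2d(np.asarray(self.bone_beads, dtype=float))
        object.__setattr__(self, "bone_beads", beads)
        object.__setattr__(self, "head_center", as_point(self.head_center))
        all_pts = np.vstack([beads, self.prosthetic_beads()])
        diff = all_pts[:, None, :] - all_pts[None, :, :]
        d = np.linalg.norm(diff, axis=-1)
        np.fill_diagonal(d, np.inf)
        if d.min() <= 2 * self.bead_diameter:
            raise ValueError(
                f"bead separation {d.min():.2f} mm must exceed twice the "
                f"bead diameter ({2 * self.bead_diameter:.2f} mm)"
            )

    def prosthetic_beads(self) -> np.ndarray:
        return _ring_points(self.ring_n_beads, self.ring_diameter)

    def bone_landmarks(self) -> LandmarkSet:
        labels = tuple(f"bone_{i + 1}" for i in range(len(self.bone_beads)))
        return LandmarkSet(labels, self.bone_beads, "bone")

    def prosthetic_landmarks(self) -> LandmarkSet:
        labels = tuple(f"cup_{i + 1}" for i in range(self.ring_n_beads))
        return LandmarkSet(labels, self.prosthetic_beads(), "prosthetic")

    def anatomy_landmarks(self) -> LandmarkSet:
        labels = tuple(_DEFAULT_ANATOMY)
        return LandmarkSet(
            labels, np.array([_DEFAULT_ANATOMY[l] for l in labels]), "anatomical"
        )


@dataclass(frozen=True)
class GroundTruth:
    """What the generator actually did: the oracle for recovery tests.

    ``reposition`` moved the whole assembly; ``implant_motion`` moved only
    the prosthetic beads, expressed about the (true) prosthetic centroid.
    With zero noise, ``true_*`` arrays reproduce the emitted landmark sets
    exactly.
    """

    reposition: RigidTransform
    implant_motion: RigidTransform
    true_reference_bone: np.ndarray
    true_reference_prosthetic: np.ndarray
    true_target_bone: np.ndarray
    true_target_prosthetic: np.ndarray
    noise_sd: float
    labels: Optional[tuple] = None

    def expected_motion(self) -> RigidTransform:
        """Target-to-reference implant transform the analysis should find."""
        return self.implant_motion.inverse()

    def expected_dof(self) -> np.ndarray:
        """Expected (rx, ry, rz, tx, ty, tz) about the reference prosthetic centroid."""
        from .kinematics import translation_about_point

        t = self.expected_motion()
        c = self.true_reference_prosthetic.mean(axis=0)
        return np.concatenate(
            [t.euler_angles().as_array(), translation_about_point(t, c)]
        )


def implant_motion_about_centroid(
    spec: PhantomSpec,
    angles: Sequence[float] = (0.0, 0.0, 0.0),
    translation: Sequence[float] = (0.0, 0.0, 0.0),
) -> RigidTransform:
    """Implant motion rotating about the spec's prosthetic centroid."""
    c = spec.prosthetic_beads().mean(axis=0)
    return RigidTransform.rotation_about_point(angles, c, translation)


def random_repositioning(
    rng: np.random.Generator,
    max_rotation_deg: float = 10.0,
    max_translation_mm: float = 20.0,
) -> RigidTransform:
    """Random whole-body repositioning between examinations.

    Uniform Euler angles within +/- ``max_rotation_deg`` per axis and a
    uniform translation within +/- ``max_translation_mm`` per axis --
    the scale of lifting a phantom off the scanner bed and laying it back
    down arbitrarily.
    """
    angles = rng.uniform(-max_rotation_deg, max_rotation_deg, size=3)
    t = rng.uniform(-max_translation_mm, max_translation_mm, size=3)
    return RigidTransform.from_euler(angles, t)


def _noisy(points: np.ndarray, noise_sd: float, rng: np.random.Generator) -> np.ndarray:
    if noise_sd == 0:
        return points.copy()
    return points + rng.normal(0.0, noise_sd, size=points.shape)


def simulate_landmark_study(
    spec: PhantomSpec,
    reposition: RigidTransform | None = None,
    implant_motion: RigidTransform | None = None,
    noise_sd: float = 0.0,
    seed: int | np.random.Generator = 0,
    include_anatomy: bool = False,
    study_type: str = "double_examination",
) -> tuple[StudyPair, GroundTruth]:
    """One landmark-level study with known ground truth.

    The reference examination observes the spec's bead positions; the
    target observes the same assembly after ``implant_motion`` (prosthetic
    beads only, about their centroid) followed by ``reposition`` (whole
    assembly).  Independent isotropic Gaussian localization noise of SD
    ``noise_sd`` (mm) is added to every observed landmark of both
    examinations.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    reposition = reposition or RigidTransform.identity()
    implant_motion = implant_motion or RigidTransform.identity()
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )

    bone = spec.bone_landmarks()
    prosthetic = spec.prosthetic_landmarks()
    true_ref_bone = bone.points
    true_ref_pros = prosthetic.points
    true_tgt_bone = reposition.transform_points(true_ref_bone)
    true_tgt_pros = reposition.transform_points(
        implant_motion.transform_points(true_ref_pros)
    )

    pair = StudyPair(
        reference_bone=bone.with_points(_noisy(true_ref_bone, noise_sd, rng)),
        reference_prosthetic=prosthetic.with_points(
            _noisy(true_ref_pros, noise_sd, rng)
        ),
        target_bone=bone.with_points(_noisy(true_tgt_bone, noise_sd, rng)),
        target_prosthetic=prosthetic.with_points(
            _noisy(true_tgt_pros, noise_sd, rng)
        ),
        anatomy=spec.anatomy_landmarks() if include_anatomy else None,
        study_type=study_type,
    )
    truth = GroundTruth(
        reposition=reposition,
        implant_motion=implant_motion,
        true_reference_bone=true_ref_bone,
        true_reference_prosthetic=true_ref_pros,
        true_target_bone=true_tgt_bone,
        true_target_prosthetic=true_tgt_pros,
        noise_sd=noise_sd,
    )
    return pair, truth


def antithetic_noise_pair(
    pair: StudyPair, noise_sd: float, seed: int | np.random.Generator
) -> tuple:
    """Two noisy copies of a (noiseless) study with mirrored noise.

    Draws one set of i.i.d. N(0, noise_sd) landmark perturbations and
    applies it with both signs, giving an antithetic pair: each study is a
    valid noisy observation, but first-order noise effects cancel in the
    pair average.  Used to estimate recovery *bias* without the
    Monte-Carlo fluctuation of independent draws.
    """
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    sets = (
        pair.reference_bone,
        pair.reference_prosthetic,
        pair.target_bone,
        pair.target_prosthetic,
    )
    eps = [rng.normal(0.0, noise_sd, s.points.shape) for s in sets]

    def perturbed(sign: float) -> StudyPair:
        rb, rp, tb, tp = (
            s.with_points(s.points + sign * e) for s, e in zip(sets, eps)
        )
        return StudyPair(
            reference_bone=rb,
            reference_prosthetic=rp,
            target_bone=tb,
            target_prosthetic=tp,
            anatomy=pair.anatomy,
            study_type=pair.study_type,
        )

    return perturbed(+1.0), perturbed(-1.0)


def _positions_rng(seed: int) -> tuple:
    ss = np.random.SeedSequence(seed)
    pos_ss, noise_ss = ss.spawn(2)
    return np.random.default_rng(pos_ss), noise_ss


def simulate_model_experiment(
    spec: PhantomSpec,
    n_positions: int = 25,
    n_selected: int = 15,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> list:
    """The full null-design experiment: all pairs of repositioned scans.

    ``n_positions`` independent repositionings are generated; all unordered
    pairs of the first ``n_selected`` become studies (count C(n_selected, 2),
    e.g. 105 for 15), each with zero implant motion and fresh localization
    noise per examination.  Returns a list of (StudyPair, GroundTruth).
    """
    if n_selected < 2:
        raise ValueError("need at least 2 selected positions to form a pair")
    if n_selected > n_positions:
        raise ValueError(
            f"n_selected={n_selected} exceeds n_positions={n_positions}"
        )
    trials = simulate_repeated_trials(
        spec, n_positions, n_selected, noise_sd, seed, n_trials=1
    )
    return trials[0]


def simulate_repeated_trials(
    spec: PhantomSpec,
    n_positions: int = 25,
    n_selected: int = 15,
    noise_sd: float = 0.0,
    seed: int = 0,
    n_trials: int = 2,
    redesignation_sd: float | None = None,
) -> list:
    """Repeated-trial version of :func:`simulate_model_experiment`.

    The phantom positions are fixed by ``seed`` and shared across trials.
    The landmark error has two parts: a scan-level component of SD
    ``noise_sd`` (partial-volume and artifact distortion of the beads in
    that particular volume, identical every time the volume is re-marked)
    and a per-trial re-designation component of SD ``redesignation_sd``
    (default ``noise_sd / 5``) -- re-marking the same volume lands almost
    on the same refined centers, which is why trial-to-trial repeatability
    is far tighter than accuracy against truth.  Returns ``n_trials``
    lists of (StudyPair, GroundTruth).
    """
    if redesignation_sd is None:
        redesignation_sd = noise_sd / 5.0
    pos_rng, noise_ss = _positions_rng(seed)
    positions = [random_repositioning(pos_rng) for _ in range(n_positions)]

    bone = spec.bone_landmarks()
    prosthetic = spec.prosthetic_landmarks()
    true_bone = [p.transform_points(bone.points) for p in positions]
    true_pros = [p.transform_points(prosthetic.points) for p in positions]

    scan_ss, trial_sss = noise_ss.spawn(2)
    scan_rng = np.random.default_rng(scan_ss)
    scan_bone = [_noisy(b, noise_sd, scan_rng) for b in true_bone[:n_selected]]
    scan_pros = [_noisy(p, noise_sd, scan_rng) for p in true_pros[:n_selected]]

    trials = []
    for trial_ss in trial_sss.spawn(n_trials):
        rng = np.random.default_rng(trial_ss)
        obs_bone = [_noisy(b, redesignation_sd, rng) for b in scan_bone]
        obs_pros = [_noisy(p, redesignation_sd, rng) for p in scan_pros]
        studies = []
        for i, j in itertools.combinations(range(n_selected), 2):
            pair = StudyPair(
                reference_bone=bone.with_points(obs_bone[i]),
                reference_prosthetic=prosthetic.with_points(obs_pros[i]),
                target_bone=bone.with_points(obs_bone[j]),
                target_prosthetic=prosthetic.with_points(obs_pros[j]),
            )
            # Net repositioning between the paired examinations.
            net = compose(positions[j], positions[i].inverse())
            truth = GroundTruth(
                reposition=net,
                implant_motion=RigidTransform.identity(),
                true_reference_bone=true_bone[i],
                true_reference_prosthetic=true_pros[i],
                true_target_bone=true_bone[j],
                true_target_prosthetic=true_pros[j],
                noise_sd=noise_sd,
            )
            studies.append((pair, truth))
        trials.append(studies)
    return trials


def _sphere_fractions(
    volume_shape: tuple,
    origin: np.ndarray,
    spacing: np.ndarray,
    center: np.ndarray,
    radius: float,
    n_sub: int = 11,
    axes_matrix: np.ndarray | None = None,
) -> tuple:
    """Partial-volume overlap fractions of a sphere with grid voxels.

    Midpoint supersampling with ``n_sub``^3 points per candidate voxel.
    ``axes_matrix`` (3x3), when given, maps offsets from the center into
    the unit ball -- rows are ellipsoid axes scaled by 1/semi-axis --
    allowing deformed (elongated) beads.  Returns (index_array, fractions).
    """
    if axes_matrix is None:
        axes_matrix = np.eye(3) / radius
    sv = np.linalg.svd(axes_matrix, compute_uv=False)
    reach = 1.0 / sv.min()  # largest semi-axis of the (possibly elongated) bead
    lo = np.floor((center - reach) / spacing - origin / spacing).astype(int) - 1
    hi = np.ceil((center + reach) / spacing - origin / spacing).astype(int) + 2
    lo = np.maximum(lo, 0)
    hi = np.minimum(hi, volume_shape)
    if np.any(hi <= lo):
        raise ValueError(f"bead at {center} lies outside the voxel grid")
    ii, jj, kk = np.meshgrid(
        *(np.arange(lo[a], hi[a]) for a in range(3)), indexing="ij"
    )
    idx = np.column_stack([ii.ravel(), jj.ravel(), kk.ravel()])
    centers = origin + idx * spacing

    offs = (np.arange(n_sub) + 0.5) / n_sub - 0.5
    sub = np.stack(
        np.meshgrid(*(offs * spacing[a] for a in range(3)), indexing="ij"),
        axis=-1,
    ).reshape(-1, 3)
    # (n_voxels, n_sub^3, 3) offsets from bead center, mapped to unit ball.
    rel = centers[:, None, :] + sub[None, :, :] - center
    unit = np.einsum("ab,vsb->vsa", axes_matrix, rel)
    inside = (unit**2).sum(axis=-1) <= 1.0
    frac = inside.mean(axis=1)
    keep = frac > 0
    return idx[keep], frac[keep]


def rasterize_phantom(
    spec: PhantomSpec,
    pose: RigidTransform | None = None,
    margin_mm: float = 4.0,
    seed: int = 0,
    n_sub: int = 11,
) -> tuple:
    """Render the phantom beads into a CT-like voxel volume.

    Every bead becomes a sphere with analytic partial-volume weighting:
    each voxel's value is background + (metal - background) * (fraction of
    the voxel inside the sphere), the fraction computed by midpoint
    supersampling (``n_sub``^3 points per voxel).  The optional cup shell
    is rendered as a hemispherical metal shell for merge-artifact tests,
    and ``spec.deformed_bead`` is elongated radially.  Gaussian HU noise of
    SD ``spec.noise_sd_hu`` is added last.  Returns (VoxelVolume,
    GroundTruth) with true bead centers in world mm.
    """
    pose = pose or RigidTransform.identity()
    rng = np.random.default_rng(seed)
    spacing = np.asarray(spec.voxel_spacing, dtype=float)
    r_bead = spec.bead_diameter / 2.0

    bone = spec.bone_landmarks()
    pros = spec.prosthetic_landmarks()
    labels = bone.labels + pros.labels
    centers = pose.transform_points(np.vstack([bone.points, pros.points]))

    extra_reach = spec.cup_shell_radius if spec.include_cup_shell else 0.0
    lo_w = centers.min(axis=0) - margin_mm - extra_reach
    hi_w = centers.max(axis=0) + margin_mm + extra_reach
    # Snap the grid to the world spacing lattice: voxel centers sit at
    # integer multiples of the spacing, independent of the content bounds.
    origin = np.floor(lo_w / spacing) * spacing
    shape = tuple(np.ceil((hi_w - origin) / spacing).astype(int) + 1)

    data = np.full(shape, spec.background_intensity, dtype=float)
    amplitude = spec.metal_intensity - spec.background_intensity

    for label, center in zip(labels, centers):
        axes_matrix = np.eye(3) / r_bead
        if spec.deformed_bead == label:
            # Elongate along the radial (streak) direction from the cup
            # center; fall back to z if the bead sits at the cup center.
            cup_center = pose(np.zeros(3))
            direction = center - cup_center
            n = np.linalg.norm(direction)
            d_hat = direction / n if n > 1e-9 else np.array([0.0, 0.0, 1.0])
            # Basis: d_hat gets the long semi-axis.
            tmp = np.array([1.0, 0.0, 0.0])
            if abs(d_hat @ tmp) > 0.9:
                tmp = np.array([0.0, 1.0, 0.0])
            u = np.cross(d_hat, tmp)
            u /= np.linalg.norm(u)
            v = np.cross(d_hat, u)
            axes_matrix = np.vstack(
                [
                    d_hat / (r_bead * spec.deformity_elongation),
                    u / r_bead,
                    v / r_bead,
                ]
            )
        idx, frac = _sphere_fractions(
            shape, origin, spacing, center, r_bead, n_sub, axes_matrix
        )
        data[idx[:, 0], idx[:, 1], idx[:, 2]] += amplitude * frac

    if spec.include_cup_shell:
        _render_cup_shell(data, origin, spacing, spec, pose, amplitude)

    if spec.noise_sd_hu > 0:
        data += rng.normal(0.0, spec.noise_sd_hu, size=data.shape)

    volume = VoxelVolume(data, spacing, origin)
    truth = GroundTruth(
        reposition=pose,
        implant_motion=RigidTransform.identity(),
        true_reference_bone=centers[: len(bone)],
        true_reference_prosthetic=centers[len(bone):],
        true_target_bone=centers[: len(bone)],
        true_target_prosthetic=centers[len(bone):],
        noise_sd=0.0,
        labels=labels,
    )
    return volume, truth


def _render_cup_shell(
    data: np.ndarray,
    origin: np.ndarray,
    spacing: np.ndarray,
    spec: PhantomSpec,
    pose: RigidTransform,
    amplitude: float,
) -> None:
    """Binary-rendered hemispherical metal shell (opening toward +z)."""
    center = pose(np.zeros(3))
    axis = pose.rotation @ np.array([0.0, 0.0, 1.0])
    r_out = spec.cup_shell_radius
    r_in = r_out - spec.cup_shell_thickness
    lo = np.maximum(
        np.floor((center - r_out - origin) / spacing).astype(int), 0
    )
    hi = np.minimum(
        np.ceil((center + r_out - origin) / spacing).astype(int) + 1, data.shape
    )
    ii, jj, kk = np.meshgrid(
        *(np.arange(lo[a], hi[a]) for a in range(3)), indexing="ij"
    )
    pts = origin + np.stack([ii, jj, kk], axis=-1) * spacing
    rel = pts - center
    dist = np.linalg.norm(rel, axis=-1)
    below = (rel @ axis) <= 0  # hemisphere on the closed side
    shell = (dist >= r_in) & (dist <= r_out) & below
    sub = data[lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]]
    sub[shell] = np.maximum(sub[shell], spec.background_intensity + amplitude)
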