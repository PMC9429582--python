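"""Synthetic CT phantoms with implanted ground-truth lesions.

The study's raw scans are proprietary, so the pipeline is exercised on
synthetic long-bone phantoms: a capsule-shaped bone (cylindrical shaft
with ellipsoidal epiphyses) voxelized into a CT-like intensity volume with
Gaussian noise, plus a noiseless bone mask and a ground-truth lesion label
volume.  Lesions are focal, sharply demarcated, uniformly hypodense
defects at the distal ossification front, rendered as single spheres or
2-3 overlapping spheres (multi-lobulated, "stair-step" morphology), each
with a known analytic volume.

No CT physics is simulated; intensity contrasts are HU-like constants
(background 50, bone 700, lesion 150, noise SD 20) because the pipeline
consumes geometry and masks, not calibrated attenuation.  All randomness
flows through one seeded ``numpy.random.default_rng`` (PCG64), so a given
spec and seed reproduce bit-identical volumes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
import numpy as np

from .labels import (
    LabelMask,
    LabelVoxel,
    RegionCode,
    regions_of_joint,
)
from .lesions import Lesion, quantify_joint
from .reorient import (
    BoneMask,
    JOINT_BONE_END,
    ReorientSpec,
    ReorientedVolume,
    ScanVolume,
    VoxelSpacing,
    compute_moment_frame,
    extract_joint_subvolume,
    map_to_original,
    resample_to_grid,
)

__all__ = [
    "INTENSITY_BACKGROUND",
    "INTENSITY_BONE",
    "INTENSITY_LESION",
    "NOISE_SD",
    "LesionSpec",
    "PhantomSpec",
    "PhantomTruth",
    "TruthLesion",
    "generate_bone",
    "implant_lesions",
    "rotation_matrix",
    "label_mask_from_grid",
    "add_specks",
    "recover_pig",
    "PigResult",
    "generate_cohort",
    "simulate_relabelling",
]

INTENSITY_BACKGROUND = 50.0
INTENSITY_BONE = 700.0
INTENSITY_LESION = 150.0
NOISE_SD = 20.0


def rotation_matrix(tilt_deg: float, azimuth_deg: float, roll_deg: float = 0.0) -> np.ndarray:
    """Rotation taking bone-local axes into scan axes: roll about local z,
    then tilt the long axis away from scan +z toward the azimuth direction."""
    t, a, r = (math.radians(v) for v in (tilt_deg, azimuth_deg, roll_deg))
    rz = np.array([[math.cos(r), -math.sin(r), 0], [math.sin(r), math.cos(r), 0], [0, 0, 1.0]])
    ry = np.array([[math.cos(t), 0, math.sin(t)], [0, 1.0, 0], [-math.sin(t), 0, math.cos(t)]])
    ra = np.array([[math.cos(a), -math.sin(a), 0], [math.sin(a), math.cos(a), 0], [0, 0, 1.0]])
    return ra @ ry @ rz


@dataclass(frozen=True)
class LesionSpec:
    """One implanted defect: sphere or 2-3 overlapping spheres.

    ``center_mm`` and lobe offsets are in bone-local coordinates (long axis
    = local z, distal = +z).  ``lobes`` are (offset, radius_mm) pairs; a
    single-lobe lesion has one entry with zero offset.
    """

    region: RegionCode
    center_mm: tuple[float, float, float]
    lobes: tuple[tuple[tuple[float, float, float], float], ...]

    @classmethod
    def sphere(cls, region: RegionCode, center_mm, radius_mm: float) -> "LesionSpec":
        return cls(region=region, center_mm=tuple(center_mm),
                   lobes=((((0.0, 0.0, 0.0)), float(radius_mm)),))

    def analytic_volume_mm3(self, resolution_mm: float = 0.05) -> float:
        """Volume of the union of lobes; closed form for one sphere, fine
        sub-grid integration for multi-lobed shapes."""
        if len(self.lobes) == 1:
            return 4.0 / 3.0 * math.pi * self.lobes[0][1] ** 3
        centers = np.array([o for o, _ in self.lobes], dtype=float)
        radii = np.array([r for _, r in self.lobes], dtype=float)
        lo = (centers - radii[:, None]).min(axis=0) - resolution_mm
        hi = (centers + radii[:, None]).max(axis=0) + resolution_mm
        axes = [np.arange(l, h, resolution_mm) for l, h in zip(lo, hi)]
        gx, gy, gz = np.meshgrid(*axes, indexing="ij")
        inside = np.zeros(gx.shape, dtype=bool)
        for (cx, cy, cz), r in zip(centers, radii):
            inside |= (gx - cx) ** 2 + (gy - cy) ** 2 + (gz - cz) ** 2 <= r * r
        return float(inside.sum()) * resolution_mm**3


@dataclass(frozen=True)
class PhantomSpec:
    """Full description of one synthetic bone volume.

    Defaults emulate the acquisition geometry of the cohort scans
    (512 x 512 in-plane voxels, 1.25 mm slice thickness, around a thousand
    slices); smaller grids can be requested for fast pipeline runs.
    """

    seed: int
    bone_id: str = "femur"
    bone_length_mm: float = 220.0
    shaft_radius_mm: float = 14.0
    epiphysis_radii_mm: tuple[float, float, float] = (30.0, 28.0, 24.0)
    orientation: tuple[float, float, float] = (0.0, 0.0, 0.0)  # tilt, azimuth, roll (deg)
    spacing: VoxelSpacing = field(default_factory=lambda: VoxelSpacing(0.7, 0.7, 1.25))
    dims: tuple[int, int, int] = (512, 512, 1000)
    lesions: tuple[LesionSpec, ...] = ()

    @property
    def rotation(self) -> np.ndarray:
        return rotation_matrix(*self.orientation)

    @property
    def center_mm(self) -> np.ndarray:
        return (np.asarray(self.dims, dtype=float) - 1.0) / 2.0 * self.spacing.array


@dataclass(frozen=True)
class TruthLesion:
    region: RegionCode
    n_voxels: int  # in the original scan grid
    voxel_volume_mm3: float  # n_voxels x original voxel volume
    analytic_volume_mm3: float
    center_xyz_mm: tuple[float, float, float]


@dataclass
class PhantomTruth:
    """Ground truth of an implanted phantom: per-lesion records plus the
    region-coded label volume in original-scan space."""

    lesions: list[TruthLesion]
    label_volume: np.ndarray  # uint8 region codes, original scan dims


def _local_coords_slice(spec: PhantomSpec, k: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Bone-local coordinates of every voxel centre in slice k."""
    nx, ny, _ = spec.dims
    sp = spec.spacing.array
    x = np.arange(nx) * sp[0] - spec.center_mm[0]
    y = np.arange(ny) * sp[1] - spec.center_mm[1]
    gx, gy = np.meshgrid(x, y, indexing="ij")
    gz = np.full_like(gx, k * sp[2] - spec.center_mm[2])
    rt = spec.rotation.T  # scan -> local
    qx = rt[0, 0] * gx + rt[0, 1] * gy + rt[0, 2] * gz
    qy = rt[1, 0] * gx + rt[1, 1] * gy + rt[1, 2] * gz
    qz = rt[2, 0] * gx + rt[2, 1] * gy + rt[2, 2] * gz
    return qx, qy, qz


def _inside_bone(spec: PhantomSpec, qx, qy, qz) -> np.ndarray:
    ex, ey, ez = spec.epiphysis_radii_mm
    half = spec.bone_length_mm / 2.0
    zc = half - ez  # epiphysis centres at +-zc
    r2 = spec.shaft_radius_mm**2
    inside = (np.abs(qz) <= zc) & (qx**2 + qy**2 <= r2)
    for sign in (1.0, -1.0):
        inside |= (qx / ex) ** 2 + (qy / ey) ** 2 + ((qz - sign * zc) / ez) ** 2 <= 1.0
    return inside


def generate_bone(spec: PhantomSpec) -> tuple[ScanVolume, BoneMask]:
    """Voxelize the capsule bone and render a noisy CT-like volume.

    The mask is the noiseless geometry.  Raises if the rotated bone reaches
    the grid boundary (it would be clipped).
    """
    ex, ey, ez = spec.epiphysis_radii_mm
    if min(ex, ey, ez) <= 0 or spec.shaft_radius_mm <= 0 or spec.bone_length_mm <= 0:
        raise ValueError("bone dimensions must be positive")
    if 2 * ez > spec.bone_length_mm:
        raise ValueError("epiphyses longer than the bone")

    nx, ny, nz = spec.dims
    mask = np.zeros(spec.dims, dtype=bool)
    for k in range(nz):
        qx, qy, qz = _local_coords_slice(spec, k)
        mask[:, :, k] = _inside_bone(spec, qx, qy, qz)

    if not mask.any():
        raise ValueError("bone does not intersect the grid")
    hit = np.argwhere(mask)
    if (hit.min(axis=0) == 0).any() or (hit.max(axis=0) == np.array(spec.dims) - 1).any():
        raise ValueError("bone exceeds the scan grid; enlarge dims or shrink the bone")

    rng = np.random.default_rng(spec.seed)
    intens = np.full(spec.dims, INTENSITY_BACKGROUND, dtype=np.float32)
    intens[mask] = INTENSITY_BONE
    intens += rng.standard_normal(spec.dims, dtype=np.float32) * NOISE_SD
    return ScanVolume(intensities=intens, spacing=spec.spacing), BoneMask(
        voxels=mask, bone_id=spec.bone_id
    )


def implant_lesions(
    scan: ScanVolume, mask: BoneMask, spec: PhantomSpec
) -> tuple[ScanVolume, PhantomTruth]:
    """Carve the spec's lesions into the scan and record ground truth.

    Lesion membership is evaluated analytically (union of lobe spheres in
    bone-local coordinates) and intersected with the bone mask, so the
    ground-truth defect is exactly the hypodense volume outlined by bone.
    Overlapping lesions of different regions raise an error.
    """
    label_vol = np.zeros(spec.dims, dtype=np.uint8)
    sp = scan.spacing.array
    truth: list[TruthLesion] = []

    for les in spec.lesions:
        c = np.asarray(les.center_mm, dtype=float)
        max_r = max(r for _, r in les.lobes) + max(
            float(np.linalg.norm(o)) for o, _ in les.lobes
        )
        # candidate voxel bbox around the lesion in scan space
        center_scan = spec.rotation @ c + spec.center_mm
        lo = np.maximum(np.floor((center_scan - max_r - sp) / sp).astype(int), 0)
        hi = np.minimum(
            np.ceil((center_scan + max_r + sp) / sp).astype(int) + 1,
            np.asarray(spec.dims),
        )
        ii, jj, kk = np.meshgrid(*(np.arange(l, h) for l, h in zip(lo, hi)), indexing="ij")
        pts = np.stack([ii * sp[0], jj * sp[1], kk * sp[2]], axis=-1) - spec.center_mm
        q = pts @ spec.rotation  # scan -> local: R^T p, row-vector form
        inside = np.zeros(ii.shape, dtype=bool)
        for off, r in les.lobes:
            d = q - (c + np.asarray(off))
            inside |= (d * d).sum(axis=-1) <= r * r
        inside &= mask.voxels[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]

        sel = (ii[inside], jj[inside], kk[inside])
        existing = label_vol[sel]
        if np.any((existing != 0) & (existing != int(les.region))):
            raise ValueError("overlapping lesions of different regions")
        label_vol[sel] = int(les.region)
        n_vox = int(inside.sum())
        truth.append(
            TruthLesion(
                region=les.region,
                n_voxels=n_vox,
                voxel_volume_mm3=n_vox * scan.spacing.voxel_volume_mm3,
                analytic_volume_mm3=les.analytic_volume_mm3(),
                center_xyz_mm=tuple(center_scan),
            )
        )
        scan.intensities[sel] = INTENSITY_LESION + (
            scan.intensities[sel] - np.float32(INTENSITY_BONE)
        )  # keep the noise realisation, shift the mean

    return scan, PhantomTruth(lesions=truth, label_volume=label_vol)


# ---------------------------------------------------------------------------
# grid-space labelling helpers

def label_mask_from_grid(
    vol: ReorientedVolume, pig_id: int, joint: str, side: str
) -> LabelMask:
    """Build a LabelMask from the region-coded label grid carried by a
    reoriented (sub)volume, back-mapping every voxel to original-scan
    coordinates."""
    if vol.labels is None:
        raise ValueError("volume carries no label grid")
    idx = np.argwhere(vol.labels != 0)
    voxels = []
    if len(idx):
        xyz = map_to_original(vol, idx.astype(float))
        for (i, j, k), p in zip(idx, np.atleast_2d(xyz)):
            voxels.append(
                LabelVoxel(
                    region=RegionCode(int(vol.labels[i, j, k])),
                    ijk=(int(i), int(j), int(k)),
                    xyz=(float(p[0]), float(p[1]), float(p[2])),
                )
            )
    return LabelMask(pig_id=pig_id, joint=joint, side=side, voxels=voxels,
                     spacing=vol.spacing)


def add_specks(
    label_mask: LabelMask,
    vol: ReorientedVolume,
    rng: np.random.Generator,
    n_specks: int = 1,
    speck_voxels: int = 2,
    region: RegionCode | None = None,
) -> LabelMask:
    """Inject sub-threshold specks (1-3 grid voxels) into a label mask.

    Specks emulate accidental labelling of normal contour irregularities;
    they must be removed by the minimum-size rule.  Speck voxels are placed
    inside the bone, at least two voxels away from any existing label.
    """
    if not 1 <= speck_voxels <= 3:
        raise ValueError("a speck has 1-3 voxels")
    if vol.mask is None:
        raise ValueError("volume carries no bone mask grid")
    region = region or regions_of_joint(label_mask.joint)[0]
    occupied = np.zeros(vol.grid_dims, dtype=bool)
    for v in label_mask.voxels:
        occupied[v.ijk] = True
    from scipy import ndimage as ndi

    forbidden = ndi.binary_dilation(occupied, np.ones((5, 5, 5), dtype=bool))
    candidates = np.argwhere(vol.mask & ~forbidden)
    # keep away from grid faces so the whole speck fits
    dims = np.asarray(vol.grid_dims)
    inner = (candidates > 0).all(axis=1) & (candidates < dims - speck_voxels).all(axis=1)
    candidates = candidates[inner]
    if len(candidates) < n_specks:
        raise ValueError("no room for specks")

    voxels = list(label_mask.voxels)
    chosen = candidates[rng.choice(len(candidates), size=n_specks, replace=False)]
    for base in chosen:
        for d in range(speck_voxels):  # a short run of voxels along i
            ijk = (int(base[0]) + d, int(base[1]), int(base[2]))
            xyz = map_to_original(vol, ijk)
            voxels.append(LabelVoxel(region=region, ijk=ijk,
                                     xyz=(float(xyz[0]), float(xyz[1]), float(xyz[2]))))
    return LabelMask(pig_id=label_mask.pig_id, joint=label_mask.joint,
                     side=label_mask.side, voxels=voxels, spacing=label_mask.spacing)


# ---------------------------------------------------------------------------
# cohort generation and end-to-end recovery

@dataclass
class PigResult:
    """End-to-end pipeline output for one phantom pig."""

    spec: PhantomSpec
    truth: PhantomTruth
    label_mask: LabelMask
    lesions: list[Lesion]
    grid_spacing: VoxelSpacing


def recover_pig(
    spec: PhantomSpec,
    pig_id: int = 0,
    joint: str = "stifle",
    side: str = "left",
    fraction: float = 0.33,
    margin_fraction: float = 0.05,
    grid_dims: tuple[int, int, int] | None = None,
    min_voxels: int = 4,
    n_specks: int = 0,
    speck_seed: int | None = None,
) -> PigResult:
    """Run the full pipeline on one phantom: generate, implant, reorient,
    extract the joint sub-volume, label from ground truth, quantify."""
    bone, _end = JOINT_BONE_END[joint]
    if bone != spec.bone_id:
        raise ValueError(f"joint {joint!r} needs a {bone} phantom")
    scan, mask = generate_bone(spec)
    scan, truth = implant_lesions(scan, mask, spec)
    frame = compute_moment_frame(mask, spec.spacing)
    rspec = ReorientSpec(bone_id=spec.bone_id, grid_dims=grid_dims,
                         margin_fraction=margin_fraction)
    vol = resample_to_grid(scan, mask, frame, rspec, labels=truth.label_volume)
    sub = extract_joint_subvolume(vol, joint, fraction=fraction)
    label_mask = label_mask_from_grid(sub.volume, pig_id, joint, side)
    if n_specks:
        rng = np.random.default_rng(spec.seed if speck_seed is None else speck_seed)
        label_mask = add_specks(label_mask, sub.volume, rng, n_specks=n_specks)
    lesions = quantify_joint(label_mask, vol.spacing, min_voxels=min_voxels,
                             grid_dims=sub.volume.grid_dims)
    return PigResult(spec=spec, truth=truth, label_mask=label_mask, lesions=lesions,
                     grid_spacing=vol.spacing)


_STIFLE_QUADRANTS = {
    (1, 1): RegionCode.MEDIAL_FEMORAL_CONDYLE,
    (-1, 1): RegionCode.LATERAL_FEMORAL_CONDYLE,
    (1, -1): RegionCode.MEDIAL_FEMORAL_TROCHLEAR_RIDGE,
    (-1, -1): RegionCode.LATERAL_FEMORAL_TROCHLEAR_RIDGE,
}


def _place_stifle_lesions(
    spec: PhantomSpec,
    rng: np.random.Generator,
    n_lesions: int,
    radius_range_mm: tuple[float, float] = (2.0, 3.5),
    lobed_prob: float = 0.25,
    max_tries: int = 400,
    max_restarts: int = 40,
) -> tuple[LesionSpec, ...]:
    """Scatter well-separated lesions near the distal ossification front.

    Centres are sampled inside the distal epiphysis, pulled toward the
    shaft-facing (ossification-front) side; the quadrant of the local x/y
    plane decides the anatomical region.  Pairwise separation exceeds the
    lobe radii plus a guard band so implanted lesions never merge; when a
    layout cannot be completed the whole placement restarts.
    """
    for _ in range(max_restarts):
        specs = _try_place_stifle_lesions(
            spec, rng, n_lesions, radius_range_mm, lobed_prob, max_tries
        )
        if specs is not None:
            return specs
    raise RuntimeError("could not place the requested number of lesions")


def _try_place_stifle_lesions(
    spec, rng, n_lesions, radius_range_mm, lobed_prob, max_tries
) -> tuple[LesionSpec, ...] | None:
    ex, ey, ez = spec.epiphysis_radii_mm
    zc = spec.bone_length_mm / 2.0 - ez  # distal epiphysis centre (+z)
    guard = 3.0 * max(spec.spacing.dx, spec.spacing.dy, spec.spacing.dz)
    placed: list[tuple[np.ndarray, float]] = []
    specs: list[LesionSpec] = []
    tries = 0
    while len(specs) < n_lesions and tries < max_tries:
        tries += 1
        r = float(rng.uniform(*radius_range_mm))
        # entirely inside the epiphysis ellipsoid, with the lesion radius as margin
        shrink = np.array([ex, ey, ez]) - r - 0.5
        if np.any(shrink <= 0):
            continue
        u = rng.uniform(-1.0, 1.0, size=3)
        if (u**2).sum() > 1.0:
            continue
        if u[2] > 0.3:  # bias toward the shaft-facing (ossification front) side
            continue
        c = np.array([0.0, 0.0, zc]) + u * shrink
        if any(np.linalg.norm(c - pc) < r + pr + guard for pc, pr in placed):
            continue
        region = _STIFLE_QUADRANTS[(1 if c[0] >= 0 else -1, 1 if c[1] >= 0 else -1)]
        if rng.uniform() < lobed_prob:
            n_lobes = int(rng.integers(2, 4))
            lobes = [((0.0, 0.0, 0.0), r)]
            for _ in range(n_lobes - 1):
                direction = rng.standard_normal(3)
                direction /= np.linalg.norm(direction)
                off = direction * r * 0.8  # overlapping => single 26-component
                lobes.append((tuple(off), r * float(rng.uniform(0.6, 0.9))))
            # every lobe must stay inside the epiphysis so the analytic
            # union volume equals the defect outlined by bone
            epi_centre = np.array([0.0, 0.0, zc])
            ok = True
            for off, lr in lobes:
                semi = np.array([ex, ey, ez]) - lr - 0.5
                if np.any(semi <= 0) or (((c + np.asarray(off) - epi_centre) / semi) ** 2).sum() > 1.0:
                    ok = False
                    break
            if not ok:
                continue
            reach = max(np.linalg.norm(o) + lr for o, lr in lobes)
            if any(np.linalg.norm(c - pc) < reach + pr + guard for pc, pr in placed):
                continue
            specs.append(LesionSpec(region=region, center_mm=tuple(c), lobes=tuple(lobes)))
            placed.append((c, reach))
        else:
            specs.append(LesionSpec.sphere(region, tuple(c), r))
            placed.append((c, r))
    if len(specs) < n_lesions:
        return None
    return tuple(specs)


def generate_cohort(
    n_pigs: int,
    seed: int,
    dims: tuple[int, int, int] = (512, 512, 1000),
    spacing: VoxelSpacing | None = None,
    mean_lesions_per_joint: float = 3.0,
    max_lesions_per_joint: int = 5,
    radius_range_mm: tuple[float, float] = (2.0, 3.5),
    joint: str = "stifle",
) -> list[PhantomSpec]:
    """Specs for a cohort of femur phantoms with randomised size,
    orientation and lesion burden (Poisson lesion counts, at least one).

    Tilt is limited to 40 degrees so the distal end of every bone stays in
    the +z half of the scan, as for a recumbent animal.
    """
    if n_pigs < 1:
        raise ValueError("n_pigs must be >= 1")
    if joint != "stifle":
        raise NotImplementedError("cohort generator currently emits femur/stifle phantoms")
    spacing = spacing or VoxelSpacing(0.7, 0.7, 1.25)
    rng = np.random.default_rng(seed)
    # bone scaled to the grid so it always fits after rotation
    grid_mm = (np.asarray(dims) - 1) * spacing.array
    length = float(min(0.55 * grid_mm[2], 220.0))
    specs = []
    for pig in range(1, n_pigs + 1):
        scale = float(rng.uniform(0.9, 1.1))
        sub_seed = int(rng.integers(0, 2**31 - 1))
        base = PhantomSpec(
            seed=sub_seed,
            bone_id="femur",
            bone_length_mm=length * scale,
            shaft_radius_mm=0.065 * length * scale,
            epiphysis_radii_mm=tuple(f * length * scale for f in (0.135, 0.125, 0.11)),
            orientation=(
                float(rng.uniform(0.0, 40.0)),
                float(rng.uniform(0.0, 360.0)),
                float(rng.uniform(0.0, 360.0)),
            ),
            spacing=spacing,
            dims=dims,
        )
        n_lesions = min(max_lesions_per_joint, max(1, int(rng.poisson(mean_lesions_per_joint))))
        lesions = _place_stifle_lesions(base, rng, n_lesions,
                                        radius_range_mm=radius_range_mm)
        specs.append(replace(base, lesions=lesions))
    return specs


def simulate_relabelling(
    positivity: dict[tuple, bool], flip_prob: float, rng: np.random.Generator
) -> dict[tuple, bool]:
    """Second labelling of the same region instances, flipping each
    positivity call independently with ``flip_prob``."""
    if not 0.0 <= flip_prob <= 1.0:
        raise ValueError("flip_prob must be a probability")
    return {k: (not v if rng.uniform() < flip_prob else v) for k, v in positivity.items()}
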