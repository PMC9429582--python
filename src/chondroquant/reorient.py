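"""Moment-based reorientation of long bones onto fixed grids.

A segmented bone mask from a whole-body CT scan is reduced to its first
image moments (centroid) and the eigen-frame of its second central moment
tensor.  The bone is then resampled into a fixed-size grid whose first axis
runs along the bone's long principal axis, so that transverse slices are
perpendicular to the long axis regardless of limb position in the original
scan.  Because the grid size is fixed per bone, the voxel spacing of the
new volume varies with the scale of the individual bone.  An exact affine
back-map from grid indices to original-scan coordinates is stored with
every reoriented volume, so labels applied on the grid can be translated
back into the original scan.

Coordinate convention: 0-based indices, voxel centres, physical units mm;
the centre of original-scan voxel (i, j, k) sits at (i*dx, j*dy, k*dz).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

__all__ = [
    "VoxelSpacing",
    "ScanVolume",
    "BoneMask",
    "MomentFrame",
    "ReorientSpec",
    "ReorientedVolume",
    "JointSubvolume",
    "DEFAULT_GRIDS",
    "JOINT_BONE_END",
    "compute_moment_frame",
    "resample_to_grid",
    "map_to_original",
    "map_from_original",
    "extract_joint_subvolume",
]

BONES = ("humerus", "femur", "tibia")

#: Fixed grid sizes (n_long, n_a, n_b) of the reoriented volumes, per bone.
DEFAULT_GRIDS: dict[str, tuple[int, int, int]] = {
    "humerus": (256, 128, 128),
    "femur": (300, 150, 150),
    "tibia": (300, 128, 128),
}

#: Which bone and which end of its long axis each joint is extracted from.
JOINT_BONE_END: dict[str, tuple[str, str]] = {
    "shoulder": ("humerus", "proximal"),
    "elbow": ("humerus", "distal"),
    "stifle": ("femur", "distal"),
    "hock": ("tibia", "distal"),
}

_EIG_TIE_RTOL = 1e-9


@dataclass(frozen=True)
class VoxelSpacing:
    """Physical voxel size in mm; ``dz`` is the slice thickness."""

    dx: float
    dy: float
    dz: float = 1.25

    def __post_init__(self) -> None:
        if not (self.dx > 0 and self.dy > 0 and self.dz > 0):
            raise ValueError(f"voxel spacing must be strictly positive, got {self}")

    @property
    def array(self) -> np.ndarray:
        return np.array([self.dx, self.dy, self.dz], dtype=float)

    @property
    def voxel_volume_mm3(self) -> float:
        return self.dx * self.dy * self.dz


@dataclass
class ScanVolume:
    """A 3D attenuation volume indexed ``[i, j, k]`` -> (x, y, z)."""

    intensities: np.ndarray
    spacing: VoxelSpacing

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities)
        if self.intensities.ndim != 3:
            raise ValueError("intensity grid must be 3-dimensional")

    @property
    def dims(self) -> tuple[int, int, int]:
        return self.intensities.shape


@dataclass
class BoneMask:
    """Binary bone segmentation co-registered with a ScanVolume."""

    voxels: np.ndarray
    bone_id: str

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=bool)
        if self.voxels.ndim != 3:
            raise ValueError("mask must be 3-dimensional")
        if self.bone_id not in BONES:
            raise ValueError(f"unknown bone_id {self.bone_id!r}; expected one of {BONES}")


@dataclass
class MomentFrame:
    """Centroid and principal axes of a bone mask.

    ``axes`` rows are orthonormal and ordered long-axis first; ``extents``
    are the half-lengths (mm) of the mask's voxel centres projected on each
    axis, measured about the centroid.
    """

    centroid: np.ndarray
    axes: np.ndarray  # (3, 3), row i = i-th principal axis
    extents: np.ndarray  # (3,) half-lengths in mm
    eigenvalues: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        self.centroid = np.asarray(self.centroid, dtype=float)
        self.axes = np.asarray(self.axes, dtype=float)
        self.extents = np.asarray(self.extents, dtype=float)
        g = self.axes @ self.axes.T
        if not np.allclose(g, np.eye(3), atol=1e-8):
            raise ValueError("axes must be orthonormal")
        if np.linalg.det(self.axes) < 0:
            raise ValueError("axes must form a right-handed triad")


@dataclass(frozen=True)
class ReorientSpec:
    """Target grid for one bone.

    margin_fraction pads the bone's principal-axis bounding box on each
    side before it is fitted to the fixed grid.
    """

    bone_id: str
    grid_dims: tuple[int, int, int] | None = None
    margin_fraction: float = 0.05

    def __post_init__(self) -> None:
        if self.bone_id not in BONES:
            raise ValueError(f"unknown bone_id {self.bone_id!r}")
        if self.grid_dims is None:
            object.__setattr__(self, "grid_dims", DEFAULT_GRIDS[self.bone_id])
        dims = tuple(int(d) for d in self.grid_dims)
        if len(dims) != 3 or any(d < 2 for d in dims):
            raise ValueError(f"grid_dims must be three integers >= 2, got {self.grid_dims}")
        object.__setattr__(self, "grid_dims", dims)
        if not (0.0 <= self.margin_fraction < 0.5):
            raise ValueError("margin_fraction must be in [0, 0.5)")


@dataclass
class ReorientedVolume:
    """Fixed-grid, bone-aligned volume with an exact back-map.

    ``backmap`` is a 4x4 affine taking grid indices (i, j, k, 1) to
    original-scan (x, y, z, 1) in mm.  ``spacing`` is the per-axis grid
    voxel size, which varies with the scale of the individual bone.
    """

    intensities: np.ndarray
    spacing: VoxelSpacing
    frame: MomentFrame
    backmap: np.ndarray
    bone_id: str
    mask: np.ndarray | None = None
    labels: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.backmap = np.asarray(self.backmap, dtype=float)
        if self.backmap.shape != (4, 4):
            raise ValueError("backmap must be a 4x4 affine")

    @property
    def grid_dims(self) -> tuple[int, int, int]:
        return self.intensities.shape


@dataclass
class JointSubvolume:
    """End-of-bone sub-grid of a ReorientedVolume containing one joint."""

    joint: str
    end: str
    fraction: float
    volume: ReorientedVolume
    parent_slice: slice

    @property
    def grid_dims(self) -> tuple[int, int, int]:
        return self.volume.grid_dims


def _fix_axis_sign(axis: np.ndarray, references: tuple[np.ndarray, ...]) -> np.ndarray:
    """Orient ``axis`` to have non-negative dot product with the first
    reference direction it is not perpendicular to."""
    for ref in references:
        d = float(axis @ ref)
        if abs(d) > 1e-12:
            return axis if d >= 0 else -axis
    return axis


def compute_moment_frame(mask: BoneMask, spacing: VoxelSpacing) -> MomentFrame:
    """First moments plus the eigen-frame of the second central moments.

    The long axis (largest eigenvalue of the central moment tensor) comes
    first.  Signs are fixed deterministically: the long axis points toward
    scan +z, the second axis toward +x (falling back to +y, +z when
    perpendicular), and the third axis completes a right-handed triad.

    Raises ``ValueError`` on an empty mask.  A degenerate moment tensor
    (repeated eigenvalues within relative tolerance) emits a warning; the
    frame is still returned with the documented lexicographic tie-break.
    """
    idx = np.argwhere(mask.voxels)
    if idx.size == 0:
        raise ValueError("empty bone mask")
    pts = idx * spacing.array
    centroid = pts.mean(axis=0)
    centered = pts - centroid
    cov = (centered.T @ centered) / len(pts)

    eigval, eigvec = np.linalg.eigh(cov)  # ascending
    order = np.argsort(eigval)[::-1]
    eigval = eigval[order]
    eigvec = eigvec[:, order]

    scale = max(float(eigval[0]), 1.0)
    ties = np.isclose(eigval[:-1], eigval[1:], rtol=_EIG_TIE_RTOL, atol=_EIG_TIE_RTOL * scale)
    degenerate = bool(ties.any()) or float(eigval[0]) <= 0.0
    if degenerate:
        warnings.warn(
            "degenerate moment tensor (repeated or zero eigenvalues); "
            "axis order resolved by deterministic tie-break",
            RuntimeWarning,
            stacklevel=2,
        )

    ez = np.array([0.0, 0.0, 1.0])
    ex = np.array([1.0, 0.0, 0.0])
    ey = np.array([0.0, 1.0, 0.0])
    a1 = _fix_axis_sign(eigvec[:, 0], (ez, ex, ey))
    a2 = _fix_axis_sign(eigvec[:, 1], (ex, ey, ez))
    if degenerate:
        # lexicographic tie-break after sign fixing: larger row first
        if tuple(np.round(a2, 12)) > tuple(np.round(a1, 12)) and np.isclose(
            eigval[0], eigval[1], rtol=_EIG_TIE_RTOL, atol=_EIG_TIE_RTOL * scale
        ):
            a1, a2 = a2, a1
    a3 = np.cross(a1, a2)  # right-handed by construction

    axes = np.vstack([a1, a2, a3])
    proj = centered @ axes.T
    extents = np.abs(proj).max(axis=0) if len(proj) else np.zeros(3)
    return MomentFrame(centroid=centroid, axes=axes, extents=extents, eigenvalues=eigval)


def _grid_affine(frame: MomentFrame, grid_dims: tuple[int, int, int],
                 grid_spacing: np.ndarray) -> np.ndarray:
    """4x4 affine: grid index -> original-scan mm, grid centred on the
    centroid with axis 0 along the long axis."""
    linear = frame.axes.T * grid_spacing  # columns = axes scaled by spacing
    half = (np.asarray(grid_dims, dtype=float) - 1.0) / 2.0
    translation = frame.centroid - linear @ half
    affine = np.eye(4)
    affine[:3, :3] = linear
    affine[:3, 3] = translation
    return affine


def resample_to_grid(
    scan: ScanVolume,
    mask: BoneMask,
    frame: MomentFrame,
    spec: ReorientSpec,
    labels: np.ndarray | None = None,
    fill_value: float = 0.0,
) -> ReorientedVolume:
    """Resample a scan into the bone-aligned fixed grid.

    Per-axis grid spacing is chosen so the bone's moment-frame bounding box
    plus ``margin_fraction`` on each side exactly fills the grid:
    ``spacing_i = 2 * extent_i * (1 + 2*margin) / n_i``.  Intensities are
    interpolated trilinearly; the bone mask and any label volume use
    nearest-neighbour interpolation (labels are categorical).
    """
    if mask.bone_id != spec.bone_id:
        raise ValueError(f"spec is for {spec.bone_id!r} but mask is {mask.bone_id!r}")
    if mask.voxels.shape != scan.dims:
        raise ValueError("mask dims do not match scan dims")
    if labels is not None and labels.shape != scan.dims:
        raise ValueError("label volume dims do not match scan dims")

    n = np.asarray(spec.grid_dims, dtype=float)
    full_lengths = 2.0 * frame.extents * (1.0 + 2.0 * spec.margin_fraction)
    grid_spacing = full_lengths / n
    if np.any(grid_spacing <= 0):
        raise ValueError(
            "bone extent implies non-positive grid spacing "
            f"(extents={frame.extents}); mask may be degenerate"
        )

    affine = _grid_affine(frame, spec.grid_dims, grid_spacing)

    ii, jj, kk = np.meshgrid(
        *(np.arange(d, dtype=float) for d in spec.grid_dims), indexing="ij"
    )
    ijk = np.stack([ii, jj, kk])  # (3, n0, n1, n2)
    world = np.einsum("ab,b...->a...", affine[:3, :3], ijk) + affine[:3, 3, None, None, None]
    coords = world / scan.spacing.array[:, None, None, None]

    intens = ndimage.map_coordinates(
        np.asarray(scan.intensities, dtype=float), coords, order=1,
        mode="constant", cval=fill_value,
    )
    mask_grid = ndimage.map_coordinates(
        mask.voxels.astype(np.uint8), coords, order=0, mode="constant", cval=0
    ).astype(bool)
    labels_grid = None
    if labels is not None:
        labels_grid = ndimage.map_coordinates(
            np.asarray(labels), coords, order=0, mode="constant", cval=0
        )

    spacing = VoxelSpacing(*(float(s) for s in grid_spacing))
    return ReorientedVolume(
        intensities=intens,
        spacing=spacing,
        frame=frame,
        backmap=affine,
        bone_id=mask.bone_id,
        mask=mask_grid,
        labels=labels_grid,
    )


def map_to_original(vol: ReorientedVolume, ijk) -> np.ndarray:
    """Map grid indices to original-scan (x, y, z) in mm.

    ``ijk`` may be one index triple or an (N, 3) array; indices may be
    fractional but must lie within the grid.
    """
    pts = np.atleast_2d(np.asarray(ijk, dtype=float))
    if pts.shape[-1] != 3:
        raise ValueError("ijk must have three components")
    dims = np.asarray(vol.grid_dims)
    if np.any(pts < 0) or np.any(pts > dims - 1):
        raise IndexError(f"grid index out of bounds for dims {vol.grid_dims}")
    xyz = pts @ vol.backmap[:3, :3].T + vol.backmap[:3, 3]
    return xyz[0] if np.ndim(ijk) == 1 else xyz


def map_from_original(vol: ReorientedVolume, xyz) -> np.ndarray:
    """Inverse back-map: original-scan mm coordinates to (fractional) grid
    indices."""
    pts = np.atleast_2d(np.asarray(xyz, dtype=float))
    inv = np.linalg.inv(vol.backmap)
    ijk = pts @ inv[:3, :3].T + inv[:3, 3]
    return ijk[0] if np.ndim(xyz) == 1 else ijk


def extract_joint_subvolume(
    vol: ReorientedVolume, joint: str, fraction: float = 0.33
) -> JointSubvolume:
    """Extract the joint-containing end of a reoriented bone volume.

    The retained span is ``fraction`` of the long axis, measured between
    voxel centres (the axis spans ``n_long - 1`` voxel spacings), so
    ``ceil(fraction * (n_long - 1)) + 1`` transverse slices are kept from
    the designated end (grid index 0 is the proximal end).  The
    sub-volume's back-map is
    the parent's, composed with the slice offset, so every retained voxel
    maps to the same original-scan coordinates as it did in the parent.
    """
    if joint not in JOINT_BONE_END:
        raise ValueError(f"unknown joint {joint!r}; expected one of {tuple(JOINT_BONE_END)}")
    bone, end = JOINT_BONE_END[joint]
    if bone != vol.bone_id:
        raise ValueError(f"joint {joint!r} belongs to the {bone}, not the {vol.bone_id}")
    if not (0.0 < fraction <= 1.0):
        raise ValueError("fraction must be in (0, 1]")

    n_long = vol.grid_dims[0]
    n_keep = min(n_long, max(1, math.ceil(fraction * (n_long - 1)) + 1))
    sl = slice(0, n_keep) if end == "proximal" else slice(n_long - n_keep, n_long)

    offset = np.eye(4)
    offset[0, 3] = sl.start
    sub = ReorientedVolume(
        intensities=vol.intensities[sl],
        spacing=vol.spacing,
        frame=vol.frame,
        backmap=vol.backmap @ offset,
        bone_id=vol.bone_id,
        mask=None if vol.mask is None else vol.mask[sl],
        labels=None if vol.labels is None else vol.labels[sl],
    )
    return JointSubvolume(joint=joint, end=end, fraction=fraction, volume=sub,
                          parent_slice=sl)
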