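"""NIfTI-1 volume I/O and back-map sidecars.

Scans, bone masks and reoriented volumes are stored as NIfTI-1 files
(spacing carried in the header affine); the exact grid-to-original-scan
affine of a reoriented volume travels in a JSON sidecar next to the
volume, so labels applied on the grid can always be translated back.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np

from .reorient import BoneMask, MomentFrame, ReorientedVolume, ScanVolume, VoxelSpacing

__all__ = [
    "write_scan",
    "read_scan",
    "write_mask",
    "read_mask",
    "write_reoriented",
    "read_reoriented",
]


def _spacing_affine(spacing: VoxelSpacing) -> np.ndarray:
    return np.diag([spacing.dx, spacing.dy, spacing.dz, 1.0])


def _spacing_from_header(img) -> VoxelSpacing:
    dx, dy, dz = (float(z) for z in img.header.get_zooms()[:3])
    return VoxelSpacing(dx, dy, dz)


def write_scan(scan: ScanVolume, path: str | Path) -> None:
    img = nib.Nifti1Image(np.asarray(scan.intensities, dtype=np.float32),
                          _spacing_affine(scan.spacing))
    nib.save(img, str(path))


def read_scan(path: str | Path) -> ScanVolume:
    img = nib.load(str(path))
    return ScanVolume(intensities=np.asarray(img.dataobj, dtype=np.float32),
                      spacing=_spacing_from_header(img))


def write_mask(mask: BoneMask, spacing: VoxelSpacing, path: str | Path) -> None:
    img = nib.Nifti1Image(mask.voxels.astype(np.uint8), _spacing_affine(spacing))
    img.header["descrip"] = mask.bone_id.encode()
    nib.save(img, str(path))


def read_mask(path: str | Path, bone_id: str | None = None) -> tuple[BoneMask, VoxelSpacing]:
    img = nib.load(str(path))
    if bone_id is None:
        bone_id = bytes(img.header["descrip"]).split(b"\x00")[0].decode() or "femur"
    mask = BoneMask(voxels=np.asarray(img.dataobj) > 0, bone_id=bone_id)
    return mask, _spacing_from_header(img)


def write_reoriented(vol: ReorientedVolume, stem: str | Path) -> dict[str, Path]:
    """Write a reoriented volume as <stem>.nii.gz plus a <stem>.backmap.json
    sidecar (and <stem>.mask/.labels.nii.gz when carried)."""
    stem = Path(stem)
    paths: dict[str, Path] = {}
    img = nib.Nifti1Image(np.asarray(vol.intensities, dtype=np.float32), vol.backmap)
    paths["volume"] = stem.with_suffix(".nii.gz")
    nib.save(img, str(paths["volume"]))
    if vol.mask is not None:
        paths["mask"] = Path(f"{stem}.mask.nii.gz")
        nib.save(nib.Nifti1Image(vol.mask.astype(np.uint8), vol.backmap), str(paths["mask"]))
    if vol.labels is not None:
        paths["labels"] = Path(f"{stem}.labels.nii.gz")
        nib.save(nib.Nifti1Image(np.asarray(vol.labels, dtype=np.uint8), vol.backmap),
                 str(paths["labels"]))
    sidecar = {
        "backmap": vol.backmap.tolist(),
        "bone_id": vol.bone_id,
        "grid_spacing_mm": [vol.spacing.dx, vol.spacing.dy, vol.spacing.dz],
        "frame": {
            "centroid_mm": vol.frame.centroid.tolist(),
            "axes": vol.frame.axes.tolist(),
            "extents_mm": vol.frame.extents.tolist(),
        },
    }
    paths["sidecar"] = Path(f"{stem}.backmap.json")
    paths["sidecar"].write_text(json.dumps(sidecar, indent=2))
    return paths


def read_reoriented(stem: str | Path) -> ReorientedVolume:
    stem = Path(stem)
    meta = json.loads(Path(f"{stem}.backmap.json").read_text())
    img = nib.load(str(stem.with_suffix(".nii.gz")))
    mask_path = Path(f"{stem}.mask.nii.gz")
    labels_path = Path(f"{stem}.labels.nii.gz")
    frame = MomentFrame(
        centroid=np.array(meta["frame"]["centroid_mm"]),
        axes=np.array(meta["frame"]["axes"]),
        extents=np.array(meta["frame"]["extents_mm"]),
    )
    return ReorientedVolume(
        intensities=np.asarray(img.dataobj, dtype=np.float32),
        spacing=VoxelSpacing(*meta["grid_spacing_mm"]),
        frame=frame,
        backmap=np.array(meta["backmap"]),
        bone_id=meta["bone_id"],
        mask=(np.asarray(nib.load(str(mask_path)).dataobj) > 0) if mask_path.exists() else None,
        labels=(np.asarray(nib.load(str(labels_path)).dataobj).astype(np.uint8)
                if labels_path.exists() else None),
    )
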