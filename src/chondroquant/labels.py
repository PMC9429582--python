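"""Data model and I/O for region-coded labelled voxels.

A radiologist labels osteochondrosis lesions voxel by voxel on the
reoriented grids; each labelled voxel carries an anatomical region code
and the original-scan coordinates recovered through the back-map.  Thirteen
anatomical regions are used, partitioned over four joints (shoulder,
elbow, stifle, hock).  Colour in a labelling GUI is presentation only;
region identity is the integer code.

Non-lesion observations (secondary sclerosis, physeal lesions, nutrient
foraminae, ...) may be carried as an ``excluded_reason`` annotation; such
voxels never enter lesion counting.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .reorient import ReorientedVolume, VoxelSpacing, map_to_original

__all__ = [
    "RegionCode",
    "JOINTS",
    "SIDES",
    "regions_of_joint",
    "LabelVoxel",
    "LabelMask",
    "PigRecord",
    "read_labels",
    "write_labels",
    "validate_mask",
]

JOINTS = ("shoulder", "elbow", "stifle", "hock")
SIDES = ("left", "right")

LABEL_CSV_COLUMNS = ["pig_id", "joint", "side", "region", "i", "j", "k", "x", "y", "z"]


class RegionCode(enum.IntEnum):
    """The 13 anatomical regions in which lesions are labelled."""

    GLENOID_CAVITY = 1
    HUMERAL_HEAD = 2
    MEDIAL_HUMERAL_CONDYLE = 3
    LATERAL_HUMERAL_CONDYLE = 4
    MEDIAL_RADIAL_HEAD = 5
    LATERAL_RADIAL_HEAD = 6
    MEDIAL_FEMORAL_TROCHLEAR_RIDGE = 7
    LATERAL_FEMORAL_TROCHLEAR_RIDGE = 8
    MEDIAL_FEMORAL_CONDYLE = 9
    LATERAL_FEMORAL_CONDYLE = 10
    DISTAL_INTERMEDIATE_RIDGE_OF_TIBIA = 11
    MEDIAL_HALF_OF_TALUS = 12
    LATERAL_HALF_OF_TALUS = 13

    @property
    def joint(self) -> str:
        return _REGION_JOINT[int(self)]

    @property
    def display_name(self) -> str:
        return _REGION_NAMES[int(self)]


_REGION_JOINT = {
    1: "shoulder", 2: "shoulder",
    3: "elbow", 4: "elbow", 5: "elbow", 6: "elbow",
    7: "stifle", 8: "stifle", 9: "stifle", 10: "stifle",
    11: "hock", 12: "hock", 13: "hock",
}

_REGION_NAMES = {
    1: "Glenoid cavity",
    2: "Humeral head",
    3: "Medial humeral condyle",
    4: "Lateral humeral condyle",
    5: "Medial radial head",
    6: "Lateral radial head",
    7: "Medial femoral trochlear ridge",
    8: "Lateral femoral trochlear ridge",
    9: "Medial femoral condyle",
    10: "Lateral femoral condyle",
    11: "Distal intermediate ridge of tibia",
    12: "Medial half of talus",
    13: "Lateral half of talus",
}


def regions_of_joint(joint: str) -> tuple[RegionCode, ...]:
    if joint not in JOINTS:
        raise ValueError(f"unknown joint {joint!r}")
    return tuple(r for r in RegionCode if r.joint == joint)


@dataclass(frozen=True)
class LabelVoxel:
    """One classified voxel: region code, reoriented-grid index and the
    original-scan coordinates it maps back to."""

    region: RegionCode
    ijk: tuple[int, int, int]
    xyz: tuple[float, float, float]
    excluded_reason: str | None = None


@dataclass
class LabelMask:
    """All labelled voxels for one joint of one pig (one side)."""

    pig_id: int
    joint: str
    side: str
    voxels: list[LabelVoxel] = field(default_factory=list)
    spacing: VoxelSpacing | None = None

    def __post_init__(self) -> None:
        if self.joint not in JOINTS:
            raise ValueError(f"unknown joint {self.joint!r}")
        if self.side not in SIDES:
            raise ValueError(f"side must be one of {SIDES}, got {self.side!r}")
        seen: set[tuple[int, int, int]] = set()
        for v in self.voxels:
            if v.ijk in seen:
                raise ValueError(f"duplicate labelled voxel at ijk={v.ijk}")
            seen.add(v.ijk)
        # region/joint consistency is report-only, see validate_mask

    @property
    def lesion_voxels(self) -> list[LabelVoxel]:
        """Voxels that enter lesion counting (excluded annotations dropped)."""
        return [v for v in self.voxels if v.excluded_reason is None]

    def __len__(self) -> int:
        return len(self.voxels)


@dataclass(frozen=True)
class PigRecord:
    pig_id: int
    breed: str
    age_days: float
    weight_kg: float

    _BREEDS = ("Landrace", "Duroc", "SyntheticA", "SyntheticB")

    def __post_init__(self) -> None:
        if self.breed not in self._BREEDS:
            raise ValueError(f"unknown breed {self.breed!r}")
        if self.age_days <= 0 or self.weight_kg <= 0:
            raise ValueError("age and weight must be positive")


def write_labels(masks: Iterable[LabelMask], path: str | Path) -> None:
    """Serialise label masks to CSV with a deterministic row order
    (pig, joint, side, region, k, j, i ascending); lossless round trip.

    Coordinates are written as mm floats with 3 decimals.
    """
    rows = []
    for m in masks:
        for v in m.voxels:
            rows.append(
                {
                    "pig_id": m.pig_id,
                    "joint": m.joint,
                    "side": m.side,
                    "region": int(v.region),
                    "i": v.ijk[0], "j": v.ijk[1], "k": v.ijk[2],
                    "x": v.xyz[0], "y": v.xyz[1], "z": v.xyz[2],
                    "excluded_reason": v.excluded_reason or "",
                }
            )
    df = pd.DataFrame(rows, columns=LABEL_CSV_COLUMNS + ["excluded_reason"])
    if len(df):
        df = df.sort_values(
            ["pig_id", "joint", "side", "region", "k", "j", "i"], kind="mergesort"
        )
    df.to_csv(path, index=False, float_format="%.3f")


def read_labels(path: str | Path) -> list[LabelMask]:
    """Parse a label CSV into masks grouped by (pig, joint, side).

    Malformed rows are reported with their line numbers; unknown region
    codes and duplicate (pig, joint, side, ijk) entries raise ``ValueError``.
    """
    df = pd.read_csv(path, dtype={"excluded_reason": str}, keep_default_na=False)
    missing = [c for c in LABEL_CSV_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"label CSV is missing columns: {missing}")
    if "excluded_reason" not in df.columns:
        df["excluded_reason"] = ""

    bad = ~df["region"].isin([int(r) for r in RegionCode])
    if bad.any():
        lines = (df.index[bad] + 2).tolist()  # +2: header + 0-based
        raise ValueError(f"unknown region code(s) on line(s) {lines}")
    dup = df.duplicated(subset=["pig_id", "joint", "side", "i", "j", "k"], keep=False)
    if dup.any():
        lines = (df.index[dup] + 2).tolist()
        raise ValueError(f"duplicate labelled voxel(s) on line(s) {lines}")

    masks = []
    for (pig, joint, side), grp in df.groupby(["pig_id", "joint", "side"], sort=True):
        voxels = [
            LabelVoxel(
                region=RegionCode(int(r.region)),
                ijk=(int(r.i), int(r.j), int(r.k)),
                xyz=(float(r.x), float(r.y), float(r.z)),
                excluded_reason=(r.excluded_reason or None),
            )
            for r in grp.itertuples()
        ]
        masks.append(LabelMask(pig_id=int(pig), joint=str(joint), side=str(side),
                               voxels=voxels))
    return masks


def validate_mask(mask: LabelMask, vol: ReorientedVolume,
                  tol_voxels: float = 0.5) -> list[str]:
    """Consistency report for a label mask against its reoriented volume.

    Flags voxels whose stored xyz deviates from the back-mapped position of
    their grid index by more than ``tol_voxels`` grid voxels, and regions
    that do not belong to the mask's joint.  Report-only: returns a list of
    human-readable flags, empty when consistent.
    """
    flags: list[str] = []
    tol_mm = tol_voxels * min(vol.spacing.dx, vol.spacing.dy, vol.spacing.dz)
    for v in mask.voxels:
        if v.region.joint != mask.joint:
            flags.append(
                f"region {v.region.display_name!r} at ijk={v.ijk} does not belong "
                f"to joint {mask.joint!r}"
            )
            continue
        expected = map_to_original(vol, v.ijk)
        err = float(np.linalg.norm(np.asarray(v.xyz) - expected))
        if err > tol_mm:
            flags.append(
                f"voxel ijk={v.ijk}: stored xyz deviates {err:.3f} mm from "
                f"back-mapped position (tolerance {tol_mm:.3f} mm)"
            )
    return flags
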