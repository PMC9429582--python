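"""From labelled voxels to discrete lesions.

One lesion is one maximal 26-connected component of labelled voxels:
voxels sharing a face, edge or corner belong to the same lesion, so both
single-lobe and multi-lobulated ("stair-step") defects count as one.
Components smaller than four voxels are discarded — a lesion must span at
least two voxels in one of the three image planes, which guards against
labelling normal contour irregularities.  Lesion size is the labelled
volume outlined by bone: voxel count times the voxel volume of the
reoriented grid the labels were drawn on.

Components are computed within each anatomical region separately; adjacent
voxels with different region codes never merge, because lesions are
counted and reported per region.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from .labels import LabelMask, RegionCode
from .reorient import VoxelSpacing

__all__ = [
    "Lesion",
    "Component",
    "connected_components_26",
    "filter_min_size",
    "lesion_volume",
    "quantify_joint",
    "lesions_to_table",
    "write_lesion_table",
    "read_lesion_table",
]

_STRUCTURE_26 = np.ones((3, 3, 3), dtype=bool)


@dataclass(frozen=True)
class Component:
    """A maximal 26-connected set of same-region labelled voxels."""

    region: RegionCode
    voxels: tuple[tuple[int, int, int], ...]

    @property
    def n_voxels(self) -> int:
        return len(self.voxels)


@dataclass
class Lesion:
    lesion_id: str
    pig_id: int
    joint: str
    side: str
    region: RegionCode
    n_voxels: int
    volume_mm3: float | None
    bbox: tuple[tuple[int, int], tuple[int, int], tuple[int, int]]
    border_flag: bool = False
    voxels: tuple[tuple[int, int, int], ...] | None = None


def connected_components_26(mask: LabelMask) -> list[Component]:
    """Partition a mask's lesion voxels into maximal 26-connected
    components, separately per region.

    Returns components ordered by (region, then first voxel in k, j, i
    order) for determinism.  Excluded-annotation voxels never participate.
    """
    by_region: dict[RegionCode, list[tuple[int, int, int]]] = {}
    for v in mask.lesion_voxels:
        by_region.setdefault(v.region, []).append(v.ijk)

    components: list[Component] = []
    for region in sorted(by_region):
        ijk = np.asarray(by_region[region], dtype=np.int64)
        lo = ijk.min(axis=0)
        shape = ijk.max(axis=0) - lo + 1
        dense = np.zeros(shape, dtype=bool)
        dense[tuple((ijk - lo).T)] = True
        labelled, n = ndimage.label(dense, structure=_STRUCTURE_26)
        for lab in range(1, n + 1):
            member = np.argwhere(labelled == lab) + lo
            voxels = tuple(sorted(map(tuple, member.tolist()),
                                  key=lambda t: (t[2], t[1], t[0])))
            components.append(Component(region=region, voxels=voxels))
        # deterministic order within region
    components.sort(key=lambda c: (int(c.region), c.voxels[0][::-1]))
    return components


def filter_min_size(
    components: Sequence[Component],
    min_voxels: int = 4,
    *,
    pig_id: int = 0,
    joint: str = "stifle",
    side: str = "left",
    grid_dims: tuple[int, int, int] | None = None,
) -> list[Lesion]:
    """Drop components below the minimum voxel count; survivors become
    lesions (volume still unset).

    A multilobed component is one lesion.  When ``grid_dims`` is given,
    lesions whose bounding box touches the grid border are flagged as at
    risk of truncation (they are retained, never excluded).
    """
    if min_voxels < 1:
        raise ValueError("min_voxels must be >= 1")
    lesions: list[Lesion] = []
    for comp in components:
        if comp.n_voxels < min_voxels:
            continue
        arr = np.asarray(comp.voxels)
        lo, hi = arr.min(axis=0), arr.max(axis=0)
        bbox = tuple((int(a), int(b)) for a, b in zip(lo, hi))
        border = False
        if grid_dims is not None:
            border = bool(np.any(lo == 0) or np.any(hi == np.asarray(grid_dims) - 1))
        lesions.append(
            Lesion(
                lesion_id=f"{pig_id}-{joint}-{side}-{int(comp.region)}-{len(lesions) + 1}",
                pig_id=pig_id,
                joint=joint,
                side=side,
                region=comp.region,
                n_voxels=comp.n_voxels,
                volume_mm3=None,
                bbox=bbox,  # type: ignore[arg-type]
                border_flag=border,
                voxels=comp.voxels,
            )
        )
    return lesions


def lesion_volume(lesion: Lesion, spacing: VoxelSpacing) -> float:
    """Lesion volume in mm^3: voxel count x voxel volume of the reoriented
    grid the labels were drawn on."""
    if spacing is None:
        raise ValueError("missing voxel spacing for lesion volume")
    return lesion.n_voxels * spacing.voxel_volume_mm3


def quantify_joint(
    mask: LabelMask,
    spacing: VoxelSpacing | None = None,
    min_voxels: int = 4,
    grid_dims: tuple[int, int, int] | None = None,
) -> list[Lesion]:
    """Full quantification of one labelled joint: 26-connected components
    per region -> minimum-size filter -> per-lesion volume."""
    spacing = spacing if spacing is not None else mask.spacing
    if spacing is None:
        raise ValueError("missing voxel spacing for lesion volume")
    comps = connected_components_26(mask)
    lesions = filter_min_size(
        comps, min_voxels,
        pig_id=mask.pig_id, joint=mask.joint, side=mask.side, grid_dims=grid_dims,
    )
    for les in lesions:
        les.volume_mm3 = lesion_volume(les, spacing)
    return lesions


def lesions_to_table(lesions: Iterable[Lesion]) -> pd.DataFrame:
    rows = [
        {
            "lesion_id": l.lesion_id,
            "pig_id": l.pig_id,
            "joint": l.joint,
            "side": l.side,
            "region": int(l.region),
            "n_voxels": l.n_voxels,
            "volume_mm3": l.volume_mm3,
            "bbox": ";".join(f"{a}:{b}" for a, b in l.bbox),
            "border_flag": l.border_flag,
        }
        for l in lesions
    ]
    return pd.DataFrame(
        rows,
        columns=["lesion_id", "pig_id", "joint", "side", "region", "n_voxels",
                 "volume_mm3", "bbox", "border_flag"],
    )


def write_lesion_table(lesions: Iterable[Lesion], path: str | Path) -> None:
    lesions_to_table(lesions).to_csv(path, sep="\t", index=False)


def read_lesion_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    df["region"] = df["region"].astype(int)
    return df
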