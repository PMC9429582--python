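"""Shared fixtures: small, fast phantom configurations.

The phantoms used in tests are deliberately smaller than the emulated
full-size scans (which default to 512 x 512 in-plane at 1.25 mm slices) so
the whole suite runs in minutes; geometry, spacing ratios and lesion sizes
stay in the regime the pipeline targets (isotropic 0.5 mm originals,
lesion radii >= 2 mm).
"""

from __future__ import annotations

import numpy as np
import pytest

from chondroquant.labels import LabelMask, LabelVoxel, RegionCode
from chondroquant.phantom import LesionSpec, PhantomSpec, recover_pig
from chondroquant.reorient import (
    ReorientSpec,
    VoxelSpacing,
    compute_moment_frame,
    resample_to_grid,
)

SMALL_DIMS = (144, 144, 240)
SMALL_SPACING = VoxelSpacing(0.5, 0.5, 0.5)


def small_femur_spec(seed: int, orientation=(25.0, 40.0, 10.0), lesions=()) -> PhantomSpec:
    return PhantomSpec(
        seed=seed,
        bone_id="femur",
        bone_length_mm=65.0,
        shaft_radius_mm=4.5,
        epiphysis_radii_mm=(9.0, 8.5, 7.2),
        orientation=orientation,
        spacing=SMALL_SPACING,
        dims=SMALL_DIMS,
        lesions=tuple(lesions),
    )


def make_label_mask(voxel_ijks, region=RegionCode.MEDIAL_FEMORAL_CONDYLE,
                    pig_id=1, joint="stifle", side="left", spacing=None) -> LabelMask:
    voxels = [LabelVoxel(region=region, ijk=tuple(map(int, v)), xyz=(0.0, 0.0, 0.0))
              for v in voxel_ijks]
    return LabelMask(pig_id=pig_id, joint=joint, side=side, voxels=voxels,
                     spacing=spacing)


@pytest.fixture(scope="session")
def femur_spec():
    return small_femur_spec(seed=11)


@pytest.fixture(scope="session")
def femur_volume(femur_spec):
    """A reoriented small femur phantom (no lesions)."""
    from chondroquant.phantom import generate_bone

    scan, mask = generate_bone(femur_spec)
    frame = compute_moment_frame(mask, femur_spec.spacing)
    vol = resample_to_grid(scan, mask, frame, ReorientSpec("femur"))
    return femur_spec, scan, mask, frame, vol


@pytest.fixture(scope="session")
def recovered_pig():
    """Full pipeline run on a phantom with three implanted lesions and one
    sub-threshold speck."""
    zc = 65.0 / 2 - 7.2  # distal epiphysis centre in bone-local coords
    lesions = (
        LesionSpec.sphere(RegionCode.MEDIAL_FEMORAL_CONDYLE, (2.5, 2.5, zc - 1.0), 3.0),
        LesionSpec.sphere(RegionCode.LATERAL_FEMORAL_CONDYLE, (-3.0, 2.0, zc - 2.0), 2.0),
        LesionSpec(
            region=RegionCode.MEDIAL_FEMORAL_TROCHLEAR_RIDGE,
            center_mm=(2.0, -3.0, zc - 2.5),
            lobes=(((0.0, 0.0, 0.0), 2.2), ((1.6, 0.0, 0.8), 1.8)),
        ),
    )
    spec = small_femur_spec(seed=23, orientation=(20.0, 130.0, 30.0), lesions=lesions)
    return recover_pig(spec, pig_id=1, n_specks=1, speck_seed=99)


def axis_aligned_ellipsoid(semi_axes=(50, 20, 20), pad=5):
    """Boolean ellipsoid mask with the given semi-axes in voxels."""
    a, b, c = semi_axes
    nx, ny, nz = 2 * a + 2 * pad + 1, 2 * b + 2 * pad + 1, 2 * c + 2 * pad + 1
    x, y, z = np.ogrid[:nx, :ny, :nz]
    cx, cy, cz = (nx - 1) / 2, (ny - 1) / 2, (nz - 1) / 2
    return ((x - cx) / a) ** 2 + ((y - cy) / b) ** 2 + ((z - cz) / c) ** 2 <= 1.0
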