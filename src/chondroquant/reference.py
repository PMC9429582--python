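"""Published cohort summary values for the 201-pig boar study.

These are the printed region- and joint-level summaries of the manually
labelled cohort (201 boars, four joints, 13 anatomical regions).  The raw
CT scans are proprietary and not distributable, so the package uses these
published tallies as *inputs*: the derived joint-table columns (mean of
region means, lesions per affected joint, per-joint prevalence), the
per-pig mean lesion count and the agreement percentage are all recomputed
from them by the aggregation code, which cross-checks the arithmetic.

Region rows carry (lesion count, affected region instances, mean lesion
volume mm^3, sample SD mm^3 or None when only one lesion exists).
"""

from __future__ import annotations

from .labels import RegionCode
from .stats import JointCounts, RegionSummary

__all__ = [
    "N_PIGS",
    "TOTAL_LESIONS",
    "TOTAL_VOLUME_MM3",
    "AGREEMENT_PAIRS",
    "AGREEMENT_AGREE",
    "REGION_SUMMARIES",
    "JOINT_COUNTS",
]

N_PIGS = 201
TOTAL_LESIONS = 6250
TOTAL_VOLUME_MM3 = 211_721.83

# repeat labelling of all regions in 10 pigs: paired observations and
# agreements on region positivity
AGREEMENT_PAIRS = 260
AGREEMENT_AGREE = 213

#: Region-level summary rows (count, affected instances, mean, SD).
REGION_SUMMARIES: list[RegionSummary] = [
    RegionSummary(RegionCode.LATERAL_FEMORAL_CONDYLE, 1797, 371, 18.55, 51.85),
    RegionSummary(RegionCode.MEDIAL_FEMORAL_CONDYLE, 1576, 400, 63.64, 133.85),
    RegionSummary(RegionCode.GLENOID_CAVITY, 976, 358, 29.24, 64.54),
    RegionSummary(RegionCode.MEDIAL_FEMORAL_TROCHLEAR_RIDGE, 532, 276, 12.39, 31.19),
    RegionSummary(RegionCode.LATERAL_FEMORAL_TROCHLEAR_RIDGE, 401, 225, 11.61, 49.26),
    RegionSummary(RegionCode.LATERAL_HUMERAL_CONDYLE, 298, 184, 37.35, 90.96),
    RegionSummary(RegionCode.MEDIAL_HUMERAL_CONDYLE, 245, 154, 45.17, 122.79),
    RegionSummary(RegionCode.HUMERAL_HEAD, 208, 135, 23.18, 101.71),
    RegionSummary(RegionCode.MEDIAL_HALF_OF_TALUS, 149, 136, 50.24, 55.50),
    RegionSummary(RegionCode.LATERAL_HALF_OF_TALUS, 57, 53, 59.72, 84.83),
    RegionSummary(RegionCode.LATERAL_RADIAL_HEAD, 8, 7, 42.88, 69.58),
    RegionSummary(RegionCode.DISTAL_INTERMEDIATE_RIDGE_OF_TIBIA, 2, 2, 7.97, 5.35),
    RegionSummary(RegionCode.MEDIAL_RADIAL_HEAD, 1, 1, 42.84, None),
]

#: Joint-level raw tallies: lesions, affected joints (of 2 x 201),
#: affected left/right pairs (of 201).
JOINT_COUNTS: dict[str, JointCounts] = {
    "stifle": JointCounts("stifle", 4306, 402, 201),
    "shoulder": JointCounts("shoulder", 1184, 371, 198),
    "elbow": JointCounts("elbow", 552, 258, 165),
    "hock": JointCounts("hock", 208, 177, 130),
}
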