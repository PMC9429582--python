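"""Cohort aggregation, critical-size translation, correlation, agreement."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from chondroquant import reference
from chondroquant.labels import RegionCode
from chondroquant.stats import (
    CriticalSizeParams,
    JointCounts,
    agreement_rate,
    classify_critical,
    counts_from_lesions,
    critical_threshold,
    joint_table,
    merge_labellings,
    pearson_r_t,
    per_joint_totals,
    per_pig_totals,
    positivity_from_lesions,
    region_table,
)


def lesion_frame(rows):
    """rows: (pig_id, joint, side, region, volume)"""
    return pd.DataFrame(
        [
            {"lesion_id": f"L{i}", "pig_id": p, "joint": j, "side": s,
             "region": int(r), "n_voxels": 10, "volume_mm3": v,
             "bbox": "0:1;0:1;0:1", "border_flag": False}
            for i, (p, j, s, r, v) in enumerate(rows)
        ]
    )


class TestRegionTable:
    def test_mean_and_sample_sd(self):
        df = lesion_frame([
            (1, "stifle", "left", RegionCode.MEDIAL_FEMORAL_CONDYLE, 10.0),
            (1, "stifle", "right", RegionCode.MEDIAL_FEMORAL_CONDYLE, 20.0),
            (2, "stifle", "left", RegionCode.MEDIAL_FEMORAL_CONDYLE, 30.0),
        ])
        rows = region_table(df, include_empty=False)
        assert len(rows) == 1
        s = rows[0]
        assert s.n_lesions == 3
        assert s.n_affected_regions == 3  # three (pig, side) instances
        assert s.mean_volume_mm3 == pytest.approx(20.0)
        assert s.sd_volume_mm3 == pytest.approx(10.0)  # sample SD, n-1

    def test_single_lesion_sd_not_applicable(self):
        df = lesion_frame([(1, "elbow", "left", RegionCode.MEDIAL_RADIAL_HEAD, 42.84)])
        (s,) = region_table(df, include_empty=False)
        assert s.sd_volume_mm3 is None

    def test_no_lesions_gives_zero_rows(self):
        rows = region_table(lesion_frame([]))
        assert len(rows) == 13
        assert all(s.n_lesions == 0 for s in rows)
        assert region_table(lesion_frame([]), include_empty=False) == []

    def test_affected_instances_counted_once(self):
        df = lesion_frame([
            (1, "stifle", "left", RegionCode.MEDIAL_FEMORAL_CONDYLE, 5.0),
            (1, "stifle", "left", RegionCode.MEDIAL_FEMORAL_CONDYLE, 7.0),
        ])
        (s,) = region_table(df, include_empty=False)
        assert s.n_lesions == 2 and s.n_affected_regions == 1

    def test_sorted_by_count_descending(self):
        summaries = reference.REGION_SUMMARIES
        counts = [s.n_lesions for s in summaries]
        assert counts == sorted(counts, reverse=True)


class TestJointTable:
    def test_single_region_mean_of_means(self):
        df = lesion_frame([
            (1, "hock", "left", RegionCode.MEDIAL_HALF_OF_TALUS, 12.0),
            (1, "hock", "left", RegionCode.MEDIAL_HALF_OF_TALUS, 18.0),
        ])
        regions = region_table(df, include_empty=False)
        counts = counts_from_lesions(df, n_pigs=2)
        table = {s.joint: s for s in joint_table(regions, counts, n_pigs=2)}
        hock = table["hock"]
        assert hock.mean_volume_mm3 == pytest.approx(15.0)
        assert hock.n_affected_joints == 1
        assert hock.lesions_per_affected_joint == pytest.approx(2.0)
        assert hock.prevalence_pct == pytest.approx(50.0)

    def test_unaffected_joint_reports_none(self):
        df = lesion_frame([(1, "hock", "left", RegionCode.MEDIAL_HALF_OF_TALUS, 12.0)])
        regions = region_table(df, include_empty=False)
        counts = counts_from_lesions(df, n_pigs=1)
        table = {s.joint: s for s in joint_table(regions, counts, n_pigs=1)}
        assert table["stifle"].lesions_per_affected_joint is None
        assert table["stifle"].mean_volume_mm3 is None
        assert table["stifle"].prevalence_pct == 0.0

    def test_region_joint_count_consistency_enforced(self):
        df = lesion_frame([(1, "hock", "left", RegionCode.MEDIAL_HALF_OF_TALUS, 12.0)])
        regions = region_table(df, include_empty=False)
        bad = {j: JointCounts(j, 0, 0, 0) for j in ("shoulder", "elbow", "stifle")}
        bad["hock"] = JointCounts("hock", 5, 1, 1)  # wrong tally
        with pytest.raises(ValueError, match="region lesion counts sum"):
            joint_table(regions, bad, n_pigs=1)

    def test_pair_prevalence_counts_pairs_not_sides(self):
        df = lesion_frame([
            (1, "stifle", "left", RegionCode.MEDIAL_FEMORAL_CONDYLE, 5.0),
            (1, "stifle", "right", RegionCode.MEDIAL_FEMORAL_CONDYLE, 5.0),
            (2, "stifle", "left", RegionCode.MEDIAL_FEMORAL_CONDYLE, 5.0),
        ])
        counts = counts_from_lesions(df, n_pigs=2)
        assert counts["stifle"].n_affected_joints == 3
        assert counts["stifle"].n_affected_pairs == 2

    def test_published_joint_totals_match_region_sums(self):
        by_joint = {j: 0 for j in ("shoulder", "elbow", "stifle", "hock")}
        for s in reference.REGION_SUMMARIES:
            by_joint[s.region.joint] += s.n_lesions
        for joint, c in reference.JOINT_COUNTS.items():
            assert by_joint[joint] == c.n_lesions
        assert sum(by_joint.values()) == reference.TOTAL_LESIONS


class TestPerPig:
    def test_totals(self):
        df = lesion_frame([
            (1, "stifle", "left", RegionCode.MEDIAL_FEMORAL_CONDYLE, 5.0),
            (1, "stifle", "right", RegionCode.LATERAL_FEMORAL_CONDYLE, 10.0),
        ])
        t = per_pig_totals(df)
        assert len(t) == 1
        assert t.loc[0, "total_volume_mm3"] == pytest.approx(15.0)
        assert t.loc[0, "mean_volume_mm3"] == pytest.approx(7.5)

    def test_empty(self):
        assert len(per_pig_totals(lesion_frame([]))) == 0

    def test_per_joint_keeps_sides_separate(self):
        df = lesion_frame([
            (1, "stifle", "left", RegionCode.MEDIAL_FEMORAL_CONDYLE, 5.0),
            (1, "stifle", "right", RegionCode.MEDIAL_FEMORAL_CONDYLE, 10.0),
        ])
        t = per_joint_totals(df, joint="stifle")
        assert len(t) == 2


class TestCriticalSize:
    def test_default_translation(self):
        cylinder, threshold = critical_threshold(CriticalSizeParams())
        assert round(cylinder, 2) == 346.30
        assert round(threshold, 2) == 204.32

    def test_bone_fraction_one(self):
        cylinder, threshold = critical_threshold(
            CriticalSizeParams(bone_fraction=1.0))
        assert threshold == pytest.approx(cylinder)

    def test_closed_form_other_width(self):
        p = CriticalSizeParams(condyle_width_mm=20.0)
        cylinder, threshold = critical_threshold(p)
        d = 0.381 * 20.0
        assert cylinder == pytest.approx(math.pi * (d / 2) ** 2 * 6.0)
        assert threshold == pytest.approx(0.59 * cylinder)

    def test_invalid_params(self):
        with pytest.raises(ValueError):
            CriticalSizeParams(depth_mm=-1)
        with pytest.raises(ValueError):
            CriticalSizeParams(bone_fraction=1.5)

    def test_classification(self):
        df = lesion_frame([
            (1, "stifle", "left", RegionCode.MEDIAL_FEMORAL_CONDYLE, v)
            for v in (100.0, 205.0, 300.0)
        ])
        res = classify_critical(df, 204.32)
        assert (res.n_above, res.n_total) == (2, 3)
        assert classify_critical(df, 500.0).n_above == 0
        # other regions ignored
        df2 = lesion_frame([(1, "stifle", "left",
                             RegionCode.LATERAL_FEMORAL_CONDYLE, 999.0)])
        assert classify_critical(df2, 204.32).n_total == 0

    def test_monotone_in_threshold(self):
        rng = np.random.default_rng(5)
        df = lesion_frame([
            (1, "stifle", "left", RegionCode.MEDIAL_FEMORAL_CONDYLE, float(v))
            for v in rng.uniform(1, 500, size=50)
        ])
        above = [classify_critical(df, t).n_above for t in np.linspace(0, 600, 25)]
        assert above == sorted(above, reverse=True)


class TestPearson:
    def test_perfect_correlation(self):
        x = np.arange(10.0)
        res = pearson_r_t(x, x)
        assert res.r == pytest.approx(1.0)
        # t diverges as r -> 1 (exactly 1 in floating point gives +inf)
        assert res.t > 1e6 and res.p < 1e-30

    def test_orthogonal_data(self):
        x = np.array([-1.0, 0.0, 1.0, 0.0])
        y = np.array([0.0, -1.0, 0.0, 1.0])
        res = pearson_r_t(x, y)
        assert res.r == pytest.approx(0.0, abs=1e-12)
        assert res.t == pytest.approx(0.0, abs=1e-12)

    def test_closed_form_t(self):
        # r = 0.5 with n = 27: t = 0.5 sqrt(25) / sqrt(0.75) = 2.8868
        r, n = 0.5, 27
        t = r * math.sqrt(n - 2) / math.sqrt(1 - r * r)
        assert t == pytest.approx(2.8868, abs=5e-5)

    def test_degenerate_input(self):
        with pytest.raises(ValueError, match="degenerate correlation input"):
            pearson_r_t([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
        with pytest.raises(ValueError):
            pearson_r_t([1.0, 2.0], [1.0, 2.0])

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.integers(0, 10**9))
    def test_t_r_identity(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 60))
        x = rng.standard_normal(n)
        y = rng.standard_normal(n) + 0.5 * x
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            return
        res = pearson_r_t(x, y)
        assert res.df == n - 2
        if abs(res.r) < 1:
            expected = res.r * math.sqrt(res.df) / math.sqrt(1 - res.r**2)
            assert abs(res.t - expected) < 1e-9


class TestAgreement:
    def test_identical_labellings(self):
        pos = {(1, "left", r): bool(r % 2) for r in range(1, 14)}
        res = agreement_rate(pos, dict(pos))
        assert res.percent == 100.0

    def test_constructed_rate(self):
        a = {(1, "left", r): True for r in range(10)}
        b = {k: (i < 7) for i, k in enumerate(a)}
        res = agreement_rate(a, b)
        assert res.n_paired == 10 and res.n_agree == 7
        assert res.percent == pytest.approx(70.0)

    def test_mismatched_instances(self):
        with pytest.raises(ValueError, match="different instance sets"):
            agreement_rate({(1, "left", 1): True}, {(1, "left", 2): True})

    def test_merge_keeps_first(self):
        a = {(1, "left", 1): True, (1, "left", 2): False}
        b = {(1, "left", 1): False, (1, "left", 2): False}
        assert merge_labellings(a, b) == a

    def test_positivity_applies_min_size_upstream(self):
        # positivity reflects the lesion table, which is already filtered
        df = lesion_frame([(1, "stifle", "left",
                            RegionCode.MEDIAL_FEMORAL_CONDYLE, 5.0)])
        instances = [(1, "left", int(RegionCode.MEDIAL_FEMORAL_CONDYLE)),
                     (1, "left", int(RegionCode.LATERAL_FEMORAL_CONDYLE))]
        pos = positivity_from_lesions(df, instances)
        assert pos[(1, "left", 9)] is True
        assert pos[(1, "left", 10)] is False
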