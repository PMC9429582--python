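"""Cohort aggregation and statistics for lesion tables.

Builds the two standard summary tables — per anatomical region (lesion
count, number of affected region instances, mean and SD of lesion volume)
and per joint (lesion count, affected joints of 2 x n_pigs, lesions per
affected joint, mean volume as the unweighted mean of the joint's region
means, affected pairs and per-joint prevalence) — plus per-pig totals,
critical-size classification, Pearson correlation with its t statistic,
and intra-observer agreement on region positivity.

Conventions: per-joint prevalence is the percentage of left/right joint
pairs with at least one affected joint; affected-joint counts use
2 x n_pigs as denominator.  SD is the sample SD (n-1) and is undefined for
a single lesion.  Rounding happens only at the presentation layer.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .labels import JOINTS, RegionCode
from .lesions import lesions_to_table

__all__ = [
    "RegionSummary",
    "JointSummary",
    "JointCounts",
    "CriticalSizeParams",
    "CriticalSizeResult",
    "CorrelationResult",
    "AgreementResult",
    "region_table",
    "joint_table",
    "counts_from_lesions",
    "per_pig_totals",
    "per_joint_totals",
    "critical_threshold",
    "classify_critical",
    "pearson_r_t",
    "agreement_rate",
    "positivity_from_lesions",
    "merge_labellings",
    "region_summaries_to_frame",
    "joint_summaries_to_frame",
]


# ---------------------------------------------------------------------------
# result containers

@dataclass(frozen=True)
class RegionSummary:
    region: RegionCode
    n_lesions: int
    n_affected_regions: int
    mean_volume_mm3: float | None
    sd_volume_mm3: float | None  # None when fewer than two lesions


@dataclass(frozen=True)
class JointSummary:
    joint: str
    n_lesions: int
    n_affected_joints: int
    lesions_per_affected_joint: float | None
    mean_volume_mm3: float | None  # mean of the joint's region means
    n_affected_pairs: int
    prevalence_pct: float


@dataclass(frozen=True)
class JointCounts:
    """Raw per-joint tallies from which the joint table derives."""

    joint: str
    n_lesions: int
    n_affected_joints: int
    n_affected_pairs: int


@dataclass(frozen=True)
class CriticalSizeParams:
    """Translation of a critical-sized cylindrical condylar defect.

    The critical defect diameter is ``diameter_fraction`` of the medial
    femoral condylar width; the cylinder has depth ``depth_mm``; only
    ``bone_fraction`` of the cylinder lies within bone and is therefore
    detectable by CT.
    """

    condyle_width_mm: float = 22.5
    diameter_fraction: float = 0.381
    depth_mm: float = 6.0
    bone_fraction: float = 0.59

    def __post_init__(self) -> None:
        if min(self.condyle_width_mm, self.diameter_fraction, self.depth_mm,
               self.bone_fraction) <= 0:
            raise ValueError("critical-size parameters must be positive")
        if self.diameter_fraction > 1 or self.bone_fraction > 1:
            raise ValueError("fractions must lie in (0, 1]")


@dataclass(frozen=True)
class CriticalSizeResult:
    n_above: int
    n_total: int
    pct: float | None


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    df: int
    t: float
    p: float
    n: int

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class AgreementResult:
    n_paired: int
    n_agree: int

    @property
    def percent(self) -> float:
        return 100.0 * self.n_agree / self.n_paired


# ---------------------------------------------------------------------------
# coercion

def _as_frame(lesions) -> pd.DataFrame:
    if isinstance(lesions, pd.DataFrame):
        return lesions
    return lesions_to_table(list(lesions))


# ---------------------------------------------------------------------------
# tables

def region_table(lesions, include_empty: bool = True) -> list[RegionSummary]:
    """Per-region summary, one row per region, sorted by lesion count
    descending (ties by region code).

    ``n_affected_regions`` counts each (pig, side, region) instance once.
    With ``include_empty`` regions without lesions appear as zero rows.
    """
    df = _as_frame(lesions)
    out: list[RegionSummary] = []
    for region in RegionCode:
        sub = df[df["region"] == int(region)] if len(df) else df
        n = int(len(sub))
        if n == 0:
            if include_empty:
                out.append(RegionSummary(region, 0, 0, None, None))
            continue
        vols = sub["volume_mm3"].to_numpy(dtype=float)
        affected = sub.groupby(["pig_id", "side"]).ngroups
        out.append(
            RegionSummary(
                region=region,
                n_lesions=n,
                n_affected_regions=int(affected),
                mean_volume_mm3=float(vols.mean()),
                sd_volume_mm3=float(vols.std(ddof=1)) if n > 1 else None,
            )
        )
    out.sort(key=lambda s: (-s.n_lesions, int(s.region)))
    return out


def counts_from_lesions(lesions, n_pigs: int) -> dict[str, JointCounts]:
    """Raw per-joint tallies from a lesion table.

    An affected joint is a (pig, side, joint) with at least one lesion; a
    pair is affected when one or both sides are.
    """
    df = _as_frame(lesions)
    counts = {}
    for joint in JOINTS:
        sub = df[df["joint"] == joint] if len(df) else df
        n_joints = sub.groupby(["pig_id", "side"]).ngroups if len(sub) else 0
        n_pairs = sub["pig_id"].nunique() if len(sub) else 0
        if n_joints > 2 * n_pigs or n_pairs > n_pigs:
            raise ValueError(f"affected counts for {joint} exceed cohort size {n_pigs}")
        counts[joint] = JointCounts(joint, int(len(sub)), int(n_joints), int(n_pairs))
    return counts


def joint_table(
    region_summaries: Sequence[RegionSummary],
    counts: Mapping[str, JointCounts],
    n_pigs: int,
) -> list[JointSummary]:
    """Per-joint summary derived from the region table plus raw tallies.

    Mean volume per lesion is the unweighted mean of the joint's region
    means ("mean of means"), taken over regions that have lesions.
    Prevalence is 100 x affected pairs / pigs.  Consistency is enforced:
    region lesion counts must sum to the joint lesion count.
    """
    if n_pigs < 1:
        raise ValueError("n_pigs must be >= 1")
    out = []
    for joint in JOINTS:
        c = counts[joint]
        regs = [s for s in region_summaries if s.region.joint == joint]
        n_from_regions = sum(s.n_lesions for s in regs)
        if n_from_regions != c.n_lesions:
            raise ValueError(
                f"{joint}: region lesion counts sum to {n_from_regions}, "
                f"joint tally says {c.n_lesions}"
            )
        means = [s.mean_volume_mm3 for s in regs if s.mean_volume_mm3 is not None]
        out.append(
            JointSummary(
                joint=joint,
                n_lesions=c.n_lesions,
                n_affected_joints=c.n_affected_joints,
                lesions_per_affected_joint=(
                    c.n_lesions / c.n_affected_joints if c.n_affected_joints else None
                ),
                mean_volume_mm3=float(np.mean(means)) if means else None,
                n_affected_pairs=c.n_affected_pairs,
                prevalence_pct=100.0 * c.n_affected_pairs / n_pigs,
            )
        )
    out.sort(key=lambda s: -s.n_lesions)
    return out


def per_pig_totals(lesions) -> pd.DataFrame:
    """One row per pig: lesion count, total and mean lesion volume (mm^3)."""
    df = _as_frame(lesions)
    if not len(df):
        return pd.DataFrame(columns=["pig_id", "n_lesions", "total_volume_mm3",
                                     "mean_volume_mm3"])
    g = df.groupby("pig_id")["volume_mm3"].agg(["count", "sum", "mean"]).reset_index()
    g.columns = ["pig_id", "n_lesions", "total_volume_mm3", "mean_volume_mm3"]
    return g


def per_joint_totals(lesions, joint: str | None = None) -> pd.DataFrame:
    """One row per (pig, side, joint): the per-joint analogue of
    :func:`per_pig_totals` (used e.g. for per-stifle-joint correlation)."""
    df = _as_frame(lesions)
    if joint is not None:
        df = df[df["joint"] == joint]
    if not len(df):
        return pd.DataFrame(columns=["pig_id", "joint", "side", "n_lesions",
                                     "total_volume_mm3", "mean_volume_mm3"])
    g = (
        df.groupby(["pig_id", "joint", "side"])["volume_mm3"]
        .agg(["count", "sum", "mean"])
        .reset_index()
    )
    g.columns = ["pig_id", "joint", "side", "n_lesions", "total_volume_mm3",
                 "mean_volume_mm3"]
    return g


# ---------------------------------------------------------------------------
# critical size

def critical_threshold(p: CriticalSizeParams = CriticalSizeParams()) -> tuple[float, float]:
    """Cylinder volume and within-bone threshold (mm^3) of the translated
    critical-sized defect.

    diameter = diameter_fraction x condylar width; cylinder volume
    pi (d/2)^2 depth; the CT-detectable threshold is bone_fraction of it.
    Values are exact; round only for presentation.
    """
    diameter = p.diameter_fraction * p.condyle_width_mm
    cylinder = math.pi * (diameter / 2.0) ** 2 * p.depth_mm
    return cylinder, p.bone_fraction * cylinder


def classify_critical(
    lesions,
    threshold_mm3: float,
    region: RegionCode = RegionCode.MEDIAL_FEMORAL_CONDYLE,
) -> CriticalSizeResult:
    """Count lesions of one region whose volume exceeds the critical-size
    threshold."""
    df = _as_frame(lesions)
    sub = df[df["region"] == int(region)] if len(df) else df
    n_total = int(len(sub))
    n_above = int((sub["volume_mm3"] > threshold_mm3).sum()) if n_total else 0
    pct = 100.0 * n_above / n_total if n_total else None
    return CriticalSizeResult(n_above=n_above, n_total=n_total, pct=pct)


# ---------------------------------------------------------------------------
# correlation and agreement

def pearson_r_t(x, y) -> CorrelationResult:
    """Pearson correlation with its t statistic on n-2 degrees of freedom.

    t = r sqrt(df) / sqrt(1 - r^2); the two-sided p comes from the t
    distribution (+-inf t for |r| = 1 gives p = 0).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D vectors")
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 observations")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("inputs must be finite")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("degenerate correlation input (zero variance)")
    r = float(sps.pearsonr(x, y).statistic)
    df = n - 2
    if abs(r) >= 1.0:
        t = math.copysign(math.inf, r)
        p = 0.0
    else:
        t = r * math.sqrt(df) / math.sqrt(1.0 - r * r)
        p = 2.0 * float(sps.t.sf(abs(t), df))
    return CorrelationResult(r=r, df=df, t=t, p=p, n=n)


def positivity_from_lesions(lesions, instances: Iterable[tuple]) -> dict[tuple, bool]:
    """Region positivity map: instance (pig_id, side, region) -> whether the
    region contains at least one lesion (after the minimum-size rule)."""
    df = _as_frame(lesions)
    present = (
        set(zip(df["pig_id"], df["side"], df["region"].astype(int)))
        if len(df)
        else set()
    )
    return {
        (p, s, int(r)): (p, s, int(r)) in present for (p, s, r) in instances
    }


def agreement_rate(
    labelling_a: Mapping[tuple, bool], labelling_b: Mapping[tuple, bool]
) -> AgreementResult:
    """Intra-observer agreement on region positivity.

    Both labellings must cover the same (pig, side, region) instances; a
    pair agrees when both call the instance positive or both negative.
    """
    if set(labelling_a) != set(labelling_b):
        raise ValueError("labellings cover different instance sets")
    n = len(labelling_a)
    if n == 0:
        raise ValueError("no paired observations")
    agree = sum(1 for k in labelling_a if labelling_a[k] == labelling_b[k])
    return AgreementResult(n_paired=n, n_agree=agree)


def merge_labellings(
    labelling_a: Mapping[tuple, bool], labelling_b: Mapping[tuple, bool]
) -> dict[tuple, bool]:
    """Resolve repeat-labelling disagreement by keeping the first labelling."""
    if set(labelling_a) != set(labelling_b):
        raise ValueError("labellings cover different instance sets")
    return {k: labelling_a[k] for k in labelling_a}


# ---------------------------------------------------------------------------
# presentation

def region_summaries_to_frame(summaries: Sequence[RegionSummary]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "region": [s.region.display_name for s in summaries],
            "region_code": [int(s.region) for s in summaries],
            "n_lesions": [s.n_lesions for s in summaries],
            "n_affected_regions": [s.n_affected_regions for s in summaries],
            "mean_volume_mm3": [s.mean_volume_mm3 for s in summaries],
            "sd_volume_mm3": [s.sd_volume_mm3 for s in summaries],
        }
    )


def joint_summaries_to_frame(summaries: Sequence[JointSummary]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "joint": [s.joint for s in summaries],
            "n_lesions": [s.n_lesions for s in summaries],
            "n_affected_joints": [s.n_affected_joints for s in summaries],
            "lesions_per_affected_joint": [s.lesions_per_affected_joint for s in summaries],
            "mean_volume_mm3": [s.mean_volume_mm3 for s in summaries],
            "n_affected_pairs": [s.n_affected_pairs for s in summaries],
            "prevalence_pct": [s.prevalence_pct for s in summaries],
        }
    )
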