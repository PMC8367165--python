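"""Study-level quality and feasibility metrics for remote wound imaging.

Implements the analysis layer of a two-arm remote self-documentation
study: the color checker detection ratio (CCDR — the fraction of
collected images in which the color reference sticker was detected),
summaries of color checker sharpness (CCS — variance of the Laplacian
over the sticker ROI), subjective-usability ratios, protocol compliance
with the capped-at-1 convention, robust duration-outlier rejection by
scaled median absolute deviation, the two-sided Wilcoxon rank-sum group
comparison, and an ordinary-least-squares duration trend.

All operations are pure: identical inputs yield identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
from scipy import stats

__all__ = [
    "AssessmentRecord",
    "GroupQualitySummary",
    "ComplianceResult",
    "RankSumResult",
    "TrendFit",
    "ccdr",
    "group_summary",
    "per_patient_summaries",
    "compliance_ratio",
    "performed_days",
    "filter_duration_outliers",
    "rank_sum_test",
    "duration_trend",
]

#: Consistency constant making the MAD estimate the standard deviation
#: under normality (1 / Phi^-1(3/4)).
MAD_SCALE = 1.4826022185056018

GROUPS = ("feedback", "basic")


@dataclass(frozen=True)
class AssessmentRecord:
    """One self-documented wound image within a home assessment.

    ``assessment_index`` is the 1-based protocol day index (day 1, 4, 7,
    ... under an every-third-day schedule). ``ccs`` is present only when
    the checker region was available for scoring; ``duration_s`` is
    attached to the first image of an assessment (time from app start to
    saving the first image) and absent on subsequent shots.
    """

    patient_id: str
    group: str
    assessment_index: int
    timestamp: Optional[str] = None
    checker_detected: bool = False
    usable_label: Optional[bool] = None
    ccs: Optional[float] = None
    duration_s: Optional[float] = None

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValueError(f"group must be one of {GROUPS}, got {self.group!r}")
        if self.assessment_index < 1:
            raise ValueError("assessment_index is 1-based")
        if self.ccs is not None and self.ccs < 0:
            raise ValueError("ccs cannot be negative")
        if self.duration_s is not None and self.duration_s <= 0:
            raise ValueError("duration_s must be positive")


@dataclass(frozen=True)
class GroupQualitySummary:
    """CCDR, CCS quartiles and usability ratio for one group or patient."""

    group: str
    n_images: int
    n_detected: int
    ccdr: float
    ccs_median: Optional[float]
    ccs_q25: Optional[float]
    ccs_q75: Optional[float]
    usable_ratio: Optional[float]
    patient_id: Optional[str] = None


@dataclass(frozen=True)
class ComplianceResult:
    """Per-patient protocol compliance, capped at 1."""

    patient_id: str
    performed_days: int
    assigned_days: int
    ratio: float


@dataclass(frozen=True)
class RankSumResult:
    """Two-sided Wilcoxon rank-sum outcome (normal approximation)."""

    statistic: float  # standardized z of the first sample's rank sum
    p_value: float
    n_a: int
    n_b: int


@dataclass(frozen=True)
class TrendFit:
    """OLS line through (assessment index, duration) points."""

    slope: float  # seconds per assessment index
    intercept: float  # seconds


def ccdr(n_detected: int, n_total: int) -> float:
    """Color checker detection ratio: detected images over collected images.

    Examples
    --------
    >>> round(ccdr(191, 199), 2)
    0.96
    """
    if n_total < 1:
        raise ValueError("CCDR is undefined for zero collected images")
    if not 0 <= n_detected <= n_total:
        raise ValueError("n_detected must lie in [0, n_total]")
    return n_detected / n_total


def _quartiles(values: Sequence[float]) -> Tuple[float, float, float]:
    q25, med, q75 = np.percentile(np.asarray(values, dtype=float), [25, 50, 75])
    return float(q25), float(med), float(q75)


def _summarize(records: List[AssessmentRecord], group: str,
               patient_id: Optional[str] = None) -> GroupQualitySummary:
    n_images = len(records)
    n_detected = sum(r.checker_detected for r in records)
    ccs_values = [r.ccs for r in records if r.ccs is not None]
    labeled = [r.usable_label for r in records if r.usable_label is not None]
    if ccs_values:
        q25, med, q75 = _quartiles(ccs_values)
    else:
        q25 = med = q75 = None
    usable_ratio = (sum(labeled) / len(labeled)) if labeled else None
    return GroupQualitySummary(
        group=group, n_images=n_images, n_detected=n_detected,
        ccdr=ccdr(n_detected, n_images),
        ccs_median=med, ccs_q25=q25, ccs_q75=q75,
        usable_ratio=usable_ratio, patient_id=patient_id,
    )


def group_summary(records: Iterable[AssessmentRecord], group: str) -> GroupQualitySummary:
    """Pooled per-image summary (CCDR, CCS quartiles, usability) of one arm."""
    sub = [r for r in records if r.group == group]
    if not sub:
        raise ValueError(f"no records in group {group!r}")
    return _summarize(sub, group)


def per_patient_summaries(records: Iterable[AssessmentRecord]) -> List[GroupQualitySummary]:
    """One summary per patient, same formulas as :func:`group_summary`.

    Patients appear in first-seen order; the group CCDR remains the
    pooled-count ratio, not the mean of these per-patient ratios.
    """
    records = list(records)
    if not records:
        raise ValueError("no records")
    by_patient: Dict[str, List[AssessmentRecord]] = {}
    for r in records:
        by_patient.setdefault(r.patient_id, []).append(r)
    return [_summarize(rs, rs[0].group, patient_id=pid)
            for pid, rs in by_patient.items()]


def compliance_ratio(performed: int, assigned_days: int = 16) -> float:
    """Performed assessment days over assigned days, capped at 1.

    A patient who assessed on more days than the protocol assigned gets a
    ratio of exactly 1.
    """
    if assigned_days < 1:
        raise ValueError("assigned_days must be at least 1")
    if performed < 0:
        raise ValueError("performed days cannot be negative")
    return min(performed / assigned_days, 1.0)


def performed_days(records: Iterable[AssessmentRecord]) -> int:
    """Distinct calendar dates (or day indices) with at least one saved image."""
    days = set()
    for r in records:
        days.add(r.timestamp[:10] if r.timestamp else r.assessment_index)
    return len(days)


def filter_duration_outliers(
    durations: Sequence[float],
) -> Tuple[List[float], List[float]]:
    """Split durations into (kept, removed) by the 3-scaled-MAD rule.

    A duration is removed when it lies more than 3 scaled median absolute
    deviations from the median, with scaled MAD = 1.4826 * median(|d -
    median|). With all-equal input the MAD is zero and only exact-median
    values survive — which is every value, so all are kept. Both outputs
    preserve input order. The filter is not idempotent in general: the
    kept subset has its own median/MAD.
    """
    ds = [float(d) for d in durations]
    if not ds:
        return [], []
    arr = np.asarray(ds)
    med = float(np.median(arr))
    mad = float(np.median(np.abs(arr - med)))
    bound = 3.0 * MAD_SCALE * mad
    kept = [d for d in ds if abs(d - med) <= bound]
    removed = [d for d in ds if abs(d - med) > bound]
    return kept, removed


def _exact_rank_sum_pvalue(w: float, n1: int, n2: int) -> float:
    """Two-sided exact p for the untied rank-sum statistic.

    Counts, by dynamic programming over subset rank sums, how many of the
    C(n1+n2, n1) equally likely rank assignments are at least as extreme
    (in |W - E[W]|) as the observed rank sum ``w``.
    """
    n = n1 + n2
    # largest achievable rank sum: the n1 top ranks
    max_sum = n1 * (2 * n - n1 + 1) // 2
    # counts[k][s] = number of k-subsets of {1..n} with rank sum s
    counts = np.zeros((n1 + 1, max_sum + 1))
    counts[0, 0] = 1.0
    for r in range(1, n + 1):
        for k in range(min(r, n1), 0, -1):
            counts[k, r:max_sum + 1] += counts[k - 1, :max_sum + 1 - r]
    dist = counts[n1]
    total = dist.sum()
    mean_w = n1 * (n + 1) / 2.0
    dev = abs(w - mean_w)
    sums = np.arange(max_sum + 1)
    extreme = dist[np.abs(sums - mean_w) >= dev - 1e-9].sum()
    return float(extreme / total)


def rank_sum_test(a: Sequence[float], b: Sequence[float]) -> RankSumResult:
    """Two-sided Wilcoxon rank-sum test.

    For small untied samples (both sizes <= 25) the p-value comes from
    the exact permutation null distribution of the rank sum, as standard
    rank-sum implementations do; otherwise from the normal approximation
    with midranks for ties, the tie-corrected variance, and a 0.5
    continuity correction. The statistic is always the standardized rank
    sum of the first sample; swapping the samples flips its sign and
    leaves the p-value unchanged.
    """
    x = np.asarray(a, dtype=float)
    y = np.asarray(b, dtype=float)
    n1, n2 = x.size, y.size
    if n1 == 0 or n2 == 0:
        raise ValueError("both samples must be nonempty")
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)  # midranks
    w = float(ranks[:n1].sum())
    n = n1 + n2
    mean_w = n1 * (n + 1) / 2.0
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(counts**3 - counts))
    var_w = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if var_w <= 0:  # all observations identical
        return RankSumResult(statistic=0.0, p_value=1.0, n_a=n1, n_b=n2)
    d = w - mean_w
    # continuity correction toward the null
    d_cc = d - 0.5 * np.sign(d) if d != 0 else 0.0
    z = float(d_cc / np.sqrt(var_w))
    no_ties = tie_term == 0
    if no_ties and max(n1, n2) <= 25:
        p = _exact_rank_sum_pvalue(w, n1, n2)
    else:
        p = float(min(1.0, 2.0 * stats.norm.sf(abs(z))))
    return RankSumResult(statistic=z, p_value=p, n_a=n1, n_b=n2)


def duration_trend(points: Sequence[Tuple[float, float]]) -> TrendFit:
    """OLS fit of duration (seconds) against assessment index.

    Raises
    ------
    ValueError
        With fewer than 2 points or all indices identical (vertical line).
    """
    pts = list(points)
    if len(pts) < 2:
        raise ValueError("need at least 2 points")
    idx = np.asarray([p[0] for p in pts], dtype=float)
    dur = np.asarray([p[1] for p in pts], dtype=float)
    if np.all(idx == idx[0]):
        raise ValueError("all assessment indices identical; trend undefined")
    res = stats.linregress(idx, dur)
    return TrendFit(slope=float(res.slope), intercept=float(res.intercept))
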