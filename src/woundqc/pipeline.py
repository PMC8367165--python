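"""Batch assessment and study report assembly.

Ties the per-image quality gate and the study metrics into the
``assess -> batch -> report`` workflow: score every image in a
directory, then summarize a manifest of assessment records into group
and per-patient quality metrics, compliance, duration statistics and
the between-group rank-sum comparison.
"""

from __future__ import annotations

import logging
from dataclasses import asdict
from pathlib import Path
from typing import Dict, Iterable, List, Optional

import numpy as np

from . import io as wio
from .gate import QualityConfig, assess_quality
from .metrics import (
    AssessmentRecord,
    GROUPS,
    compliance_ratio,
    duration_trend,
    filter_duration_outliers,
    group_summary,
    per_patient_summaries,
    performed_days,
    rank_sum_test,
)

logger = logging.getLogger("woundqc")

IMAGE_SUFFIXES = (".png", ".jpg", ".jpeg")


def batch_assess(image_dir, config: Optional[QualityConfig] = None) -> List[Dict]:
    """Assess every PNG/JPEG in a directory, in filename order.

    Returns one row per image with the decision, reasons and CCS. An
    unreadable file yields an ``error`` row and processing continues; an
    empty directory raises.
    """
    config = config or QualityConfig()
    paths = sorted(p for p in Path(image_dir).iterdir()
                   if p.suffix.lower() in IMAGE_SUFFIXES)
    if not paths:
        raise ValueError(f"no PNG/JPEG images found in {image_dir}")
    rows: List[Dict] = []
    for path in paths:
        try:
            image = wio.read_image(path)
        except Exception as e:  # unreadable/corrupt file: log and continue
            logger.warning("could not read %s: %s", path, e)
            rows.append({"image_path": path.name, "error": str(e),
                         "passed": None, "reasons": ["read_error"],
                         "ccs": None, "area_fraction": None})
            continue
        decision = assess_quality(image, config)
        rows.append({
            "image_path": path.name,
            "error": None,
            "passed": decision.passed,
            "reasons": sorted(decision.reasons),
            "ccs": (decision.sharpness.value
                    if decision.sharpness is not None else None),
            "area_fraction": decision.detection.area_fraction,
        })
    return rows


def _round(x: Optional[float], nd: int = 6) -> Optional[float]:
    return None if x is None else round(float(x), nd)


def build_report(records: Iterable[AssessmentRecord],
                 assigned_days: int = 16) -> Dict:
    """Assemble the study report from assessment records.

    Per group: pooled CCDR / CCS quartiles / usability; per patient: the
    same plus compliance; between groups: a rank-sum test on pooled
    per-image CCS and on per-patient median CCS; per group: a duration
    trend over assessment index after 3-scaled-MAD outlier removal
    (applied within patient, mirroring a per-patient timing analysis).
    """
    records = list(records)
    if not records:
        raise ValueError("no records to report on")
    patient_summaries = per_patient_summaries(records)

    report: Dict = {"groups": {}, "patients": [], "tests": {}, "compliance": {},
                    "duration": {}}
    ccs_pooled: Dict[str, List[float]] = {}
    ccs_patient_medians: Dict[str, List[float]] = {}
    for group in GROUPS:
        in_group = [r for r in records if r.group == group]
        if not in_group:
            continue
        gs = group_summary(records, group)
        report["groups"][group] = {
            "n_images": gs.n_images, "n_detected": gs.n_detected,
            "ccdr": _round(gs.ccdr),
            "ccs_median": _round(gs.ccs_median),
            "ccs_q25": _round(gs.ccs_q25), "ccs_q75": _round(gs.ccs_q75),
            "usable_ratio": _round(gs.usable_ratio),
        }
        ccs_pooled[group] = [r.ccs for r in in_group if r.ccs is not None]
        ccs_patient_medians[group] = [
            s.ccs_median for s in patient_summaries
            if s.group == group and s.ccs_median is not None]

    compliance_rows = []
    for ps in patient_summaries:
        own = [r for r in records if r.patient_id == ps.patient_id]
        days = performed_days(own)
        compliance_rows.append({
            "patient_id": ps.patient_id, "group": ps.group,
            "performed_days": days, "assigned_days": assigned_days,
            "ratio": _round(compliance_ratio(days, assigned_days)),
        })
        report["patients"].append({
            "patient_id": ps.patient_id, "group": ps.group,
            "n_images": ps.n_images, "ccdr": _round(ps.ccdr),
            "ccs_median": _round(ps.ccs_median),
            "usable_ratio": _round(ps.usable_ratio),
        })
    report["compliance"]["patients"] = compliance_rows
    for group in report["groups"]:
        ratios = [c["ratio"] for c in compliance_rows if c["group"] == group]
        report["compliance"][group] = {"median_ratio": _round(float(np.median(ratios)))}

    if all(len(ccs_pooled.get(g, [])) > 0 for g in GROUPS):
        rs = rank_sum_test(ccs_pooled["feedback"], ccs_pooled["basic"])
        report["tests"]["ccs_pooled_rank_sum"] = {
            "statistic": _round(rs.statistic), "p_value": rs.p_value,
            "n_feedback": rs.n_a, "n_basic": rs.n_b,
        }
    if all(len(ccs_patient_medians.get(g, [])) > 0 for g in GROUPS):
        rs = rank_sum_test(ccs_patient_medians["feedback"],
                           ccs_patient_medians["basic"])
        report["tests"]["ccs_patient_median_rank_sum"] = {
            "statistic": _round(rs.statistic), "p_value": rs.p_value,
            "n_feedback": rs.n_a, "n_basic": rs.n_b,
        }

    for group in report["groups"]:
        # durations filtered per patient, then pooled for the group trend
        points, kept_all, removed_all = [], [], []
        for pid in {r.patient_id for r in records if r.group == group}:
            own = [(r.assessment_index, r.duration_s)
                   for r in records
                   if r.patient_id == pid and r.duration_s is not None]
            kept, removed = filter_duration_outliers([d for _, d in own])
            removed_all.extend(removed)
            kept_set = list(kept)
            for idx, d in own:
                if d in kept_set:
                    kept_set.remove(d)
                    points.append((idx, d))
                    kept_all.append(d)
        entry: Dict = {
            "n_assessments": len(kept_all),
            "n_outliers_removed": len(removed_all),
            "median_duration_s": (_round(float(np.median(kept_all)))
                                  if kept_all else None),
        }
        distinct = {p[0] for p in points}
        if len(points) >= 2 and len(distinct) >= 2:
            trend = duration_trend(points)
            entry["trend_slope_s_per_assessment"] = _round(trend.slope)
            entry["trend_intercept_s"] = _round(trend.intercept)
        report["duration"][group] = entry
    return report
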