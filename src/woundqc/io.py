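"""Reading and writing images, manifests and configuration.

The manifest CSV carries one row per image with the columns
``patient_id, group, assessment_index, timestamp, image_path,
checker_detected, usable_label, ccs, duration_s`` (UTF-8, header
required, booleans as ``true``/``false``, missing values empty).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Iterable, List, Optional, Union

import numpy as np
import pandas as pd
from PIL import Image

from .detection import DetectionConfig
from .gate import QualityConfig
from .imaging import GrayImage, WoundImage
from .metrics import AssessmentRecord

__all__ = [
    "read_image", "write_image", "write_gray",
    "read_manifest", "write_manifest",
    "RunConfig", "load_config",
]

MANIFEST_COLUMNS = [
    "patient_id", "group", "assessment_index", "timestamp", "image_path",
    "checker_detected", "usable_label", "ccs", "duration_s",
]


def read_image(path: Union[str, Path]) -> WoundImage:
    """Load an 8-bit RGB PNG/JPEG as a :class:`WoundImage`."""
    with Image.open(path) as im:
        rgb = im.convert("RGB")
        return WoundImage(np.asarray(rgb, dtype=np.uint8))


def write_image(image: WoundImage, path: Union[str, Path]) -> None:
    Image.fromarray(image.pixels, mode="RGB").save(path)


def write_gray(gray: GrayImage, path: Union[str, Path]) -> None:
    """Write a grayscale image as 8-bit PNG (debugging aid)."""
    px = np.clip(np.rint(gray.pixels), 0, 255).astype(np.uint8)
    Image.fromarray(px, mode="L").save(path)


def _parse_bool(v) -> Optional[bool]:
    if v is None or (isinstance(v, float) and np.isnan(v)) or v == "":
        return None
    if isinstance(v, (bool, np.bool_)):
        return bool(v)
    s = str(v).strip().lower()
    if s in ("true", "1"):
        return True
    if s in ("false", "0"):
        return False
    raise ValueError(f"cannot parse boolean value {v!r}")


def read_manifest(path: Union[str, Path]) -> List[AssessmentRecord]:
    """Read assessment records from a manifest CSV."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns and c != "image_path"]
    if missing:
        raise ValueError(f"manifest is missing columns: {missing}")
    records = []
    for _, row in df.iterrows():
        records.append(AssessmentRecord(
            patient_id=row["patient_id"],
            group=row["group"],
            assessment_index=int(row["assessment_index"]),
            timestamp=row["timestamp"] or None,
            checker_detected=bool(_parse_bool(row["checker_detected"]) or False),
            usable_label=_parse_bool(row["usable_label"]),
            ccs=float(row["ccs"]) if row["ccs"] != "" else None,
            duration_s=float(row["duration_s"]) if row["duration_s"] != "" else None,
        ))
    return records


def _fmt_bool(v: Optional[bool]) -> str:
    return "" if v is None else ("true" if v else "false")


def write_manifest(records: Iterable[AssessmentRecord],
                   path: Union[str, Path],
                   image_paths: Optional[List[str]] = None) -> None:
    """Write records to a manifest CSV (deterministic, byte-stable)."""
    records = list(records)
    rows = []
    for i, r in enumerate(records):
        rows.append({
            "patient_id": r.patient_id,
            "group": r.group,
            "assessment_index": r.assessment_index,
            "timestamp": r.timestamp or "",
            "image_path": image_paths[i] if image_paths else "",
            "checker_detected": _fmt_bool(r.checker_detected),
            "usable_label": _fmt_bool(r.usable_label),
            "ccs": "" if r.ccs is None else repr(float(r.ccs)),
            "duration_s": "" if r.duration_s is None else repr(float(r.duration_s)),
        })
    pd.DataFrame(rows, columns=MANIFEST_COLUMNS).to_csv(path, index=False)


@dataclass(frozen=True)
class RunConfig:
    """Validated runtime configuration for the CLI workflow."""

    quality: QualityConfig = field(default_factory=QualityConfig)
    manifest_path: Optional[str] = None
    output_path: Optional[str] = None
    log_level: str = "INFO"


_DETECTION_FIELDS = {"min_area_fraction", "max_aspect_ratio", "grid_check",
                     "grid_min_std"}
_TOP_FIELDS = {"sharpness_threshold", "detection", "manifest_path",
               "output_path", "log_level"}


def load_config(path: Union[str, Path]) -> RunConfig:
    """Load a JSON configuration, applying documented defaults.

    Unknown keys and out-of-range thresholds raise a validation error
    naming the offending field.
    """
    with open(path, encoding="utf-8") as fh:
        raw = json.load(fh)
    if not isinstance(raw, dict):
        raise ValueError("config must be a JSON object")
    unknown = set(raw) - _TOP_FIELDS
    if unknown:
        raise ValueError(f"unknown config fields: {sorted(unknown)}")
    det_raw = raw.get("detection", {})
    if not isinstance(det_raw, dict):
        raise ValueError("field 'detection' must be an object")
    unknown = set(det_raw) - _DETECTION_FIELDS
    if unknown:
        raise ValueError(f"unknown detection fields: {sorted(unknown)}")
    try:
        detection = DetectionConfig(**det_raw)
    except (TypeError, ValueError) as e:
        raise ValueError(f"invalid detection config: {e}") from e
    kwargs = {}
    if "sharpness_threshold" in raw:
        kwargs["sharpness_threshold"] = float(raw["sharpness_threshold"])
    try:
        quality = QualityConfig(detection=detection, **kwargs)
    except ValueError as e:
        raise ValueError(f"invalid field 'sharpness_threshold': {e}") from e
    return RunConfig(
        quality=quality,
        manifest_path=raw.get("manifest_path"),
        output_path=raw.get("output_path"),
        log_level=str(raw.get("log_level", "INFO")),
    )


def save_config(config: RunConfig, path: Union[str, Path]) -> None:
    """Serialize a RunConfig back to JSON (round-trips with load_config)."""
    doc = {
        "sharpness_threshold": config.quality.sharpness_threshold,
        "detection": asdict(config.quality.detection),
        "log_level": config.log_level,
    }
    if config.manifest_path is not None:
        doc["manifest_path"] = config.manifest_path
    if config.output_path is not None:
        doc["output_path"] = config.output_path
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(doc, fh, indent=2, sort_keys=True)
        fh.write("\n")
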