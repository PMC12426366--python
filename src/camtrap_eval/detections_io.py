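"""Data model and readers/writers for detections, annotations and manifests.

The canonical interchange dialect is a plain detection CSV (UTF-8, comma
separated, header required, ``.`` decimal): columns ``image_id,class,score``
with optional ``station_id,deployment_id`` and normalized-box columns
``x_center,y_center,width,height``.  YOLO label directories and MegaDetector
batch JSON are converted into the same in-memory records at the boundary.

Boxes use the YOLO normalized center convention internally (fractions of
image width/height).  Box localization is never scored by this package, so a
single convention suffices; corner-origin inputs are converted on read.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

__all__ = [
    "FormatError",
    "VocabularyError",
    "BoundingBox",
    "PredictedDetection",
    "VerifiedAnnotation",
    "ImageRecord",
    "ClassVocabulary",
    "ROLES",
    "read_detection_table",
    "read_verified_table",
    "read_manifest",
    "parse_yolo_labels",
    "read_class_map",
    "read_megadetector_json",
    "write_results_table",
    "read_results_table",
    "write_detection_table",
    "write_verified_table",
    "write_manifest",
]

_BOX_TOL = 1e-9

ROLES = ("animal", "human", "vehicle", "empty-marker", "other")


class FormatError(ValueError):
    """Raised when an input file violates the declared format."""


class VocabularyError(ValueError):
    """Raised when a class label or index is not in the declared vocabulary."""


@dataclass(frozen=True)
class BoundingBox:
    """Axis-aligned box in normalized center convention.

    All fields are fractions of the image dimensions: ``x_center``/``y_center``
    in [0, 1], ``width``/``height`` in (0, 1].  The box must lie within the
    unit square up to a 1e-9 tolerance.
    """

    x_center: float
    y_center: float
    width: float
    height: float

    def __post_init__(self) -> None:
        vals = (self.x_center, self.y_center, self.width, self.height)
        if not all(math.isfinite(v) for v in vals):
            raise ValueError(f"bounding box fields must be finite, got {vals}")
        if not (0.0 < self.width <= 1.0 + _BOX_TOL and 0.0 < self.height <= 1.0 + _BOX_TOL):
            raise ValueError(f"box width/height must be in (0,1], got {vals}")
        for c, w in ((self.x_center, self.width), (self.y_center, self.height)):
            if c - w / 2 < -_BOX_TOL or c + w / 2 > 1.0 + _BOX_TOL:
                raise ValueError(f"box extends outside the unit square: {vals}")

    @classmethod
    def from_corner(cls, x: float, y: float, w: float, h: float) -> "BoundingBox":
        """Build from corner-origin fractional (x, y, w, h) as in MegaDetector JSON."""
        return cls(x + w / 2.0, y + h / 2.0, w, h)

    def to_corner(self) -> tuple[float, float, float, float]:
        """Inverse of :meth:`from_corner`."""
        return (self.x_center - self.width / 2.0, self.y_center - self.height / 2.0,
                self.width, self.height)


@dataclass(frozen=True)
class PredictedDetection:
    """One detector output: a class label with a confidence score on one image.

    ``score`` is the detector confidence in [0, 1]; for YOLO-family detectors
    this is the product of objectness and class confidence.
    """

    image_id: str
    class_label: str
    score: float
    box: Optional[BoundingBox] = None

    def __post_init__(self) -> None:
        if not self.class_label:
            raise ValueError("class_label must be nonempty")
        if not (math.isfinite(self.score) and 0.0 <= self.score <= 1.0):
            raise ValueError(
                f"score must be in [0,1], got {self.score!r} for image {self.image_id!r}"
            )


@dataclass(frozen=True)
class VerifiedAnnotation:
    """Ground truth for one (image, class) pair with the number of individuals."""

    image_id: str
    class_label: str
    count: int

    def __post_init__(self) -> None:
        if int(self.count) < 1:
            raise ValueError(f"count must be >= 1, got {self.count} on {self.image_id!r}")


@dataclass(frozen=True)
class ImageRecord:
    """Manifest entry mapping an image to its station and deployment."""

    image_id: str
    station_id: str
    deployment_id: str
    timestamp: Optional[str] = None
    reviewed: bool = True


@dataclass(frozen=True)
class ClassVocabulary:
    """Ordered class labels with a role tag per label.

    Roles distinguish animal classes from human/vehicle/other classes, which
    the binary (animal vs. empty) analysis excludes.
    """

    labels: tuple[str, ...]
    roles: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("vocabulary labels must be unique")
        for lab, role in self.roles.items():
            if role not in ROLES:
                raise ValueError(f"unknown role {role!r} for label {lab!r}")
            if lab not in self.labels:
                raise ValueError(f"role given for label {lab!r} not in vocabulary")

    @classmethod
    def from_labels(
        cls,
        labels: Sequence[str],
        roles: Optional[Mapping[str, str]] = None,
        *,
        human_labels: Sequence[str] = ("human", "person", "people"),
        vehicle_labels: Sequence[str] = ("vehicle",),
    ) -> "ClassVocabulary":
        """Build a vocabulary, inferring human/vehicle roles from common names."""
        inferred: dict[str, str] = {}
        for lab in labels:
            if lab in human_labels:
                inferred[lab] = "human"
            elif lab in vehicle_labels:
                inferred[lab] = "vehicle"
        if roles:
            inferred.update(roles)
        return cls(tuple(labels), inferred)

    def role(self, label: str) -> str:
        if label not in self.labels:
            raise VocabularyError(
                f"label {label!r} not in vocabulary {list(self.labels)}"
            )
        return self.roles.get(label, "animal")

    def animal_labels(self) -> tuple[str, ...]:
        return tuple(l for l in self.labels if self.role(l) == "animal")

    def __contains__(self, label: str) -> bool:
        return label in self.labels

    def __iter__(self):
        return iter(self.labels)


# ---------------------------------------------------------------------------
# CSV dialect


def _require_columns(df: pd.DataFrame, required: Sequence[str], path) -> None:
    for col in required:
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column {col!r}")


def read_detection_table(
    path, vocabulary: Optional[ClassVocabulary] = None
) -> tuple[list[PredictedDetection], list[ImageRecord]]:
    """Read the detection CSV dialect.

    Required columns: ``image_id,class,score``.  Optional: ``station_id``,
    ``deployment_id`` (yield :class:`ImageRecord` entries) and the four
    normalized-box columns.  Scores outside [0, 1] and labels outside the
    vocabulary raise errors rather than being silently dropped.
    """
    df = pd.read_csv(path, dtype={"image_id": str, "class": str}, keep_default_na=False)
    _require_columns(df, ["image_id", "class", "score"], path)
    has_box = all(c in df.columns for c in ("x_center", "y_center", "width", "height"))
    detections: list[PredictedDetection] = []
    images: dict[str, ImageRecord] = {}
    for i, rec in enumerate(df.to_dict("records")):
        label = str(rec["class"])
        score = float(rec["score"])
        if not (0.0 <= score <= 1.0):
            raise FormatError(f"{path}: row {i + 2}: score {score} outside [0,1]")
        if vocabulary is not None and label not in vocabulary:
            raise VocabularyError(
                f"{path}: row {i + 2}: unknown class {label!r}; "
                f"vocabulary is {list(vocabulary.labels)}"
            )
        box = None
        if has_box:
            xc = rec["x_center"]
            if xc not in ("", None) and not (isinstance(xc, float) and math.isnan(xc)):
                box = BoundingBox(
                    float(xc), float(rec["y_center"]),
                    float(rec["width"]), float(rec["height"]),
                )
        image_id = str(rec["image_id"])
        detections.append(PredictedDetection(image_id, label, score, box))
        if "station_id" in df.columns:
            station = str(rec["station_id"])
            deployment = (
                str(rec["deployment_id"]) if "deployment_id" in df.columns else station
            )
            images.setdefault(image_id, ImageRecord(image_id, station, deployment))
    return detections, list(images.values())


def read_verified_table(path) -> list[VerifiedAnnotation]:
    """Read verified annotations: columns ``image_id,class,count``."""
    df = pd.read_csv(path, dtype={"image_id": str, "class": str}, keep_default_na=False)
    _require_columns(df, ["image_id", "class", "count"], path)
    out: list[VerifiedAnnotation] = []
    seen: set[tuple[str, str]] = set()
    for i, rec in enumerate(df.to_dict("records")):
        key = (str(rec["image_id"]), str(rec["class"]))
        if key in seen:
            raise FormatError(f"{path}: row {i + 2}: duplicate (image, class) pair {key}")
        seen.add(key)
        out.append(VerifiedAnnotation(key[0], key[1], int(rec["count"])))
    return out


def read_manifest(path) -> list[ImageRecord]:
    """Read the image manifest: ``image_id,station_id,deployment_id[,timestamp,reviewed]``."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    _require_columns(df, ["image_id", "station_id", "deployment_id"], path)
    records: list[ImageRecord] = []
    seen: set[str] = set()
    dep_station: dict[str, str] = {}
    for i, rec in enumerate(df.to_dict("records")):
        image_id = rec["image_id"]
        if image_id in seen:
            raise FormatError(f"{path}: row {i + 2}: duplicate image_id {image_id!r}")
        seen.add(image_id)
        dep = rec["deployment_id"]
        if dep_station.setdefault(dep, rec["station_id"]) != rec["station_id"]:
            raise FormatError(
                f"{path}: deployment {dep!r} mapped to more than one station"
            )
        reviewed = str(rec.get("reviewed", "true")).strip().lower() in ("true", "1", "yes", "")
        ts = rec.get("timestamp") or None
        records.append(ImageRecord(image_id, rec["station_id"], dep, ts, reviewed))
    return records


# ---------------------------------------------------------------------------
# YOLO label directories


def read_class_map(path) -> list[str]:
    """Read a ``classes.txt`` file: one label per line, index = 0-based line number."""
    with open(path, encoding="utf-8") as fh:
        return [line.strip() for line in fh if line.strip()]


def parse_yolo_labels(
    label_dir, class_map: Sequence[str]
) -> tuple[list[PredictedDetection], list[VerifiedAnnotation]]:
    """Parse a directory of YOLO label files.

    Each file ``<image_id>.txt`` holds lines
    ``class_index x_center y_center width height [score]``.  Lines with the
    optional sixth field become predictions; lines without become annotations,
    aggregated into one count per (image, class).
    """
    label_dir = Path(label_dir)
    predictions: list[PredictedDetection] = []
    counts: dict[tuple[str, str], int] = {}
    for file in sorted(label_dir.glob("*.txt")):
        if file.name == "classes.txt":
            continue
        image_id = file.stem
        with open(file, encoding="utf-8") as fh:
            for lineno, line in enumerate(fh, start=1):
                parts = line.split()
                if not parts:
                    continue
                if len(parts) not in (5, 6):
                    raise FormatError(
                        f"{file}:{lineno}: expected 5 or 6 fields, got {len(parts)}"
                    )
                try:
                    idx = int(parts[0])
                    nums = [float(p) for p in parts[1:]]
                except ValueError as exc:
                    raise FormatError(f"{file}:{lineno}: non-numeric field ({exc})") from exc
                if not 0 <= idx < len(class_map):
                    raise VocabularyError(
                        f"{file}:{lineno}: class index {idx} out of range "
                        f"for {len(class_map)} classes"
                    )
                label = class_map[idx]
                box = BoundingBox(nums[0], nums[1], nums[2], nums[3])
                if len(parts) == 6:
                    predictions.append(PredictedDetection(image_id, label, nums[4], box))
                else:
                    counts[(image_id, label)] = counts.get((image_id, label), 0) + 1
    annotations = [
        VerifiedAnnotation(img, lab, n) for (img, lab), n in sorted(counts.items())
    ]
    return predictions, annotations


# ---------------------------------------------------------------------------
# MegaDetector batch JSON

_MD_DEFAULT_CATEGORIES = {"1": "animal", "2": "person", "3": "vehicle"}


def read_megadetector_json(path) -> tuple[list[PredictedDetection], list[str]]:
    """Read MegaDetector v5 batch output.

    Returns the detections plus the full list of image ids present in the file
    (images with an empty ``detections`` array are prediction-free but still
    listed).  Corner-origin fractional boxes are converted to the center
    convention.
    """
    try:
        with open(path, encoding="utf-8") as fh:
            payload = json.load(fh)
    except json.JSONDecodeError as exc:
        raise FormatError(f"{path}: malformed JSON ({exc})") from exc
    if "images" not in payload or not isinstance(payload["images"], list):
        raise FormatError(f"{path}: missing top-level 'images' array")
    categories = dict(_MD_DEFAULT_CATEGORIES)
    categories.update(payload.get("detection_categories", {}))
    detections: list[PredictedDetection] = []
    image_ids: list[str] = []
    for entry in payload["images"]:
        image_id = str(entry.get("file", entry.get("id", "")))
        image_ids.append(image_id)
        for det in entry.get("detections", []):
            cat = str(det["category"])
            if cat not in categories:
                raise VocabularyError(
                    f"{path}: image {image_id!r}: unknown category id {cat!r}"
                )
            box = None
            if "bbox" in det:
                box = BoundingBox.from_corner(*map(float, det["bbox"]))
            detections.append(
                PredictedDetection(image_id, categories[cat], float(det["conf"]), box)
            )
    return detections, image_ids


# ---------------------------------------------------------------------------
# Result tables


def _record_to_row(record) -> dict:
    if dataclasses.is_dataclass(record):
        row = dataclasses.asdict(record)
    elif isinstance(record, Mapping):
        row = dict(record)
    else:
        raise TypeError(f"cannot serialize record of type {type(record).__name__}")
    # flatten nested dataclass values (e.g. boxes) into columns
    flat: dict = {}
    for key, value in row.items():
        if isinstance(value, dict):
            for k2, v2 in value.items():
                flat[f"{key}_{k2}"] = v2
        else:
            flat[key] = value
    return flat


def write_results_table(records: Iterable, path, record_type=None) -> None:
    """Write homogeneous result records to CSV.

    Column order follows the record's field order; rows are sorted by
    ``class_label`` then ``threshold`` when those columns exist, so output is
    deterministic.  Floats are written at full precision (round trips to at
    least 12 significant digits).
    """
    records = list(records)
    if not records:
        if record_type is None:
            cols: list[str] = []
        else:
            cols = [f.name for f in dataclasses.fields(record_type)]
        pd.DataFrame(columns=cols).to_csv(path, index=False)
        return
    rows = [_record_to_row(r) for r in records]
    df = pd.DataFrame(rows)
    sort_cols = [c for c in ("class_label", "threshold") if c in df.columns]
    if sort_cols:
        df = df.sort_values(sort_cols, kind="mergesort").reset_index(drop=True)
    df.to_csv(path, index=False, float_format="%.17g")


def read_results_table(path) -> pd.DataFrame:
    """Read back a results CSV written by :func:`write_results_table`."""
    return pd.read_csv(path)


def write_detection_table(detections: Iterable[PredictedDetection], path,
                          manifest: Optional[Iterable[ImageRecord]] = None) -> None:
    """Write detections in the canonical CSV dialect (optionally with station columns)."""
    station: dict[str, ImageRecord] = {}
    if manifest is not None:
        station = {rec.image_id: rec for rec in manifest}
    rows = []
    for d in detections:
        row = {"image_id": d.image_id, "class": d.class_label, "score": d.score}
        if station:
            rec = station.get(d.image_id)
            if rec is None:
                raise FormatError(f"detection image {d.image_id!r} missing from manifest")
            row["station_id"] = rec.station_id
            row["deployment_id"] = rec.deployment_id
        if d.box is not None:
            row.update(
                x_center=d.box.x_center, y_center=d.box.y_center,
                width=d.box.width, height=d.box.height,
            )
        rows.append(row)
    cols = ["image_id", "class", "score"]
    if station:
        cols += ["station_id", "deployment_id"]
    if any("x_center" in r for r in rows):
        cols += ["x_center", "y_center", "width", "height"]
    pd.DataFrame(rows, columns=cols).to_csv(path, index=False, float_format="%.17g")


def write_verified_table(annotations: Iterable[VerifiedAnnotation], path) -> None:
    rows = [
        {"image_id": a.image_id, "class": a.class_label, "count": a.count}
        for a in annotations
    ]
    pd.DataFrame(rows, columns=["image_id", "class", "count"]).to_csv(path, index=False)


def write_manifest(records: Iterable[ImageRecord], path) -> None:
    rows = [
        {
            "image_id": r.image_id,
            "station_id": r.station_id,
            "deployment_id": r.deployment_id,
            "timestamp": r.timestamp or "",
            "reviewed": str(r.reviewed).lower(),
        }
        for r in records
    ]
    pd.DataFrame(
        rows, columns=["image_id", "station_id", "deployment_id", "timestamp", "reviewed"]
    ).to_csv(path, index=False)
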