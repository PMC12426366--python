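"""Empty-image filtering evaluation.

All species classes are collapsed to a single "animal" label and each image
is scored by the maximum confidence over its animal-class predictions.  At a
score threshold t an image is predicted-animal iff that maximum is >= t
(inclusive).  Sensitivity = TP/(TP+FN) and specificity = TN/(TN+FP) are
tallied at the image level over the reviewed subset; the module also
cross-tabulates two detectors' predicted-animal calls and plans manual-review
subsets (all animal predictions above a floor, a per-deployment sample of
predicted-empty images, and stratified score-bin samples for oversized
deployment-by-class strata).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np

from .detections_io import (
    ClassVocabulary,
    ImageRecord,
    PredictedDetection,
    VerifiedAnnotation,
)

__all__ = [
    "BINARY_THRESHOLD_GRID",
    "SCORE_BINS",
    "BinaryImageRecord",
    "BinaryConfusion",
    "AgreementTable",
    "ReviewItem",
    "ReviewPlan",
    "collapse_to_binary",
    "binary_confusion_sweep",
    "compare_detectors",
    "plan_review",
]

#: Default threshold grid for the binary sweep: 0.25 to 0.95 by 0.10,
#: generated by integer steps so grid points are exact.
BINARY_THRESHOLD_GRID: tuple[float, ...] = tuple(i / 100 for i in range(25, 96, 10))

#: Review score bins (0-0.25, 0.26-0.50, 0.51-0.75, 0.76-1.0).
SCORE_BINS: tuple[tuple[float, float], ...] = (
    (0.0, 0.25), (0.25, 0.50), (0.50, 0.75), (0.75, 1.0),
)


@dataclass(frozen=True)
class BinaryImageRecord:
    """One reviewed image collapsed to animal/empty with its max animal score."""

    image_id: str
    true_state: str  # "animal" | "empty"
    max_animal_score: Optional[float]


@dataclass(frozen=True)
class BinaryConfusion:
    threshold: float
    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def sensitivity(self) -> Optional[float]:
        d = self.tp + self.fn
        return self.tp / d if d else None

    @property
    def specificity(self) -> Optional[float]:
        d = self.tn + self.fp
        return self.tn / d if d else None


@dataclass(frozen=True)
class AgreementTable:
    """Cross-tabulation of two detectors' predicted-animal calls at one threshold.

    ``cells`` maps (a_predicts_animal, b_predicts_animal, true_state) to a
    count; :meth:`cell` sums over true state.
    """

    threshold: float
    cells: dict[tuple[bool, bool, str], int]

    def cell(self, a_animal: bool, b_animal: bool) -> int:
        return sum(
            n for (a, b, _), n in self.cells.items() if a == a_animal and b == b_animal
        )

    @property
    def total(self) -> int:
        return sum(self.cells.values())


@dataclass(frozen=True)
class ReviewItem:
    image_id: str
    deployment_id: str
    reason: str  # "animal-prediction" | "empty-sample" | "bin-sample"


@dataclass(frozen=True)
class ReviewPlan:
    items: tuple[ReviewItem, ...]

    def by_deployment(self) -> dict[str, list[ReviewItem]]:
        out: dict[str, list[ReviewItem]] = {}
        for it in self.items:
            out.setdefault(it.deployment_id, []).append(it)
        return out


def collapse_to_binary(
    predictions: Iterable[PredictedDetection],
    truth: Iterable[VerifiedAnnotation],
    manifest: Iterable[ImageRecord],
    vocabulary: ClassVocabulary,
    *,
    keep_nonanimal: bool = False,
) -> list[BinaryImageRecord]:
    """Collapse per-image content to an animal/empty state and a max animal score.

    Only reviewed manifest images are considered; a reviewed image with no
    annotations is a confirmed-empty image.  By default, images whose only
    content (true or predicted) is human/vehicle, and images with more than
    one true class, are excluded from the binary analysis; with
    ``keep_nonanimal=True`` they are retained and treated as "no animal".
    """
    truth_by_image: dict[str, set[str]] = {}
    for ann in truth:
        truth_by_image.setdefault(ann.image_id, set()).add(ann.class_label)
    score_by_image: dict[str, float] = {}
    pred_labels_by_image: dict[str, set[str]] = {}
    for det in predictions:
        pred_labels_by_image.setdefault(det.image_id, set()).add(det.class_label)
        if vocabulary.role(det.class_label) == "animal":
            prev = score_by_image.get(det.image_id)
            if prev is None or det.score > prev:
                score_by_image[det.image_id] = det.score

    records: list[BinaryImageRecord] = []
    for rec in manifest:
        if not rec.reviewed:
            continue
        labels = truth_by_image.get(rec.image_id, set())
        animal_labels = {l for l in labels if vocabulary.role(l) == "animal"}
        if not keep_nonanimal:
            if labels and not animal_labels:
                continue  # human/vehicle-only truth
            if len(labels) > 1:
                continue  # multi-class image
            if not labels:
                plabels = pred_labels_by_image.get(rec.image_id, set())
                if plabels and all(vocabulary.role(l) != "animal" for l in plabels):
                    continue  # only non-animal predictions on an empty image
        state = "animal" if animal_labels else "empty"
        records.append(
            BinaryImageRecord(rec.image_id, state, score_by_image.get(rec.image_id))
        )
    return records


def _validate_grid(thresholds: Sequence[float]) -> tuple[float, ...]:
    grid = tuple(float(t) for t in thresholds)
    if not grid:
        raise ValueError("threshold grid is empty")
    if any(not 0.0 <= t <= 1.0 for t in grid):
        raise ValueError("thresholds must lie in [0,1]")
    if any(b <= a for a, b in zip(grid, grid[1:])):
        raise ValueError("thresholds must be strictly increasing")
    return grid


def binary_confusion_sweep(
    records: Sequence[BinaryImageRecord],
    thresholds: Sequence[float] = BINARY_THRESHOLD_GRID,
) -> list[BinaryConfusion]:
    """Tally the animal/empty confusion at each threshold (inclusive >= t)."""
    if not records:
        raise ValueError("no binary image records to evaluate")
    grid = _validate_grid(thresholds)
    out: list[BinaryConfusion] = []
    for t in grid:
        tp = fp = fn = tn = 0
        for r in records:
            predicted = r.max_animal_score is not None and r.max_animal_score >= t
            if r.true_state == "animal":
                tp += predicted
                fn += not predicted
            else:
                fp += predicted
                tn += not predicted
        out.append(BinaryConfusion(t, tp, fp, fn, tn))
    return out


def compare_detectors(
    records_a: Sequence[BinaryImageRecord],
    records_b: Sequence[BinaryImageRecord],
    threshold: float,
) -> AgreementTable:
    """Cross-tabulate predicted-animal status under two detectors.

    Both record sets must cover exactly the same image ids (same reviewed
    subset); cells are stratified by the true image state.
    """
    a_by_id = {r.image_id: r for r in records_a}
    b_by_id = {r.image_id: r for r in records_b}
    if set(a_by_id) != set(b_by_id):
        diff = set(a_by_id) ^ set(b_by_id)
        raise ValueError(
            f"detector record sets differ on {len(diff)} image id(s)"
        )
    cells: dict[tuple[bool, bool, str], int] = {}
    for image_id, ra in a_by_id.items():
        rb = b_by_id[image_id]
        a_pred = ra.max_animal_score is not None and ra.max_animal_score >= threshold
        b_pred = rb.max_animal_score is not None and rb.max_animal_score >= threshold
        key = (a_pred, b_pred, ra.true_state)
        cells[key] = cells.get(key, 0) + 1
    return AgreementTable(float(threshold), cells)


def _bin_index(score: float) -> int:
    for i, (lo, hi) in enumerate(SCORE_BINS):
        if (score > lo or (i == 0 and score >= lo)) and score <= hi:
            return i
    raise ValueError(f"score {score} outside [0,1]")


def plan_review(
    predictions: Iterable[PredictedDetection],
    manifest: Sequence[ImageRecord],
    vocabulary: ClassVocabulary,
    *,
    threshold_floor: float = 0.25,
    empty_sample_target: int = 100,
    overflow_trigger: int = 2000,
    bin_sample_target: int = 50,
    seed: int = 0,
) -> ReviewPlan:
    """Select images for manual review.

    Per deployment: (a) every image with an animal prediction >= the floor is
    selected, except that within a deployment-by-class stratum larger than
    ``overflow_trigger`` images, a random ``bin_sample_target`` images per
    score bin are taken instead; (b) a random ``empty_sample_target``
    predicted-empty images are selected (all of them when fewer exist).
    Deterministic for a given seed.
    """
    if empty_sample_target < 1 or bin_sample_target < 1 or overflow_trigger < 1:
        raise ValueError("sampling targets must be positive")
    by_image: dict[str, ImageRecord] = {r.image_id: r for r in manifest}
    # top surviving animal prediction per image: (class, score)
    top: dict[str, tuple[str, float]] = {}
    for det in predictions:
        if det.image_id not in by_image:
            raise ValueError(f"prediction image {det.image_id!r} missing from manifest")
        if vocabulary.role(det.class_label) != "animal" or det.score < threshold_floor:
            continue
        prev = top.get(det.image_id)
        if prev is None or det.score > prev[1]:
            top[det.image_id] = (det.class_label, det.score)

    rng = np.random.default_rng(seed)
    items: list[ReviewItem] = []
    deployments: dict[str, list[ImageRecord]] = {}
    for rec in manifest:
        deployments.setdefault(rec.deployment_id, []).append(rec)

    for dep_id in sorted(deployments):
        recs = deployments[dep_id]
        strata: dict[str, list[tuple[str, float]]] = {}
        empties: list[str] = []
        for rec in sorted(recs, key=lambda r: r.image_id):
            hit = top.get(rec.image_id)
            if hit is None:
                empties.append(rec.image_id)
            else:
                strata.setdefault(hit[0], []).append((rec.image_id, hit[1]))
        for cls in sorted(strata):
            members = strata[cls]
            if len(members) > overflow_trigger:
                bins: list[list[str]] = [[] for _ in SCORE_BINS]
                for image_id, score in members:
                    bins[_bin_index(score)].append(image_id)
                for bucket in bins:
                    take = min(bin_sample_target, len(bucket))
                    if take == 0:
                        continue
                    chosen = rng.choice(len(bucket), size=take, replace=False)
                    for j in sorted(int(c) for c in chosen):
                        items.append(ReviewItem(bucket[j], dep_id, "bin-sample"))
            else:
                for image_id, _ in members:
                    items.append(ReviewItem(image_id, dep_id, "animal-prediction"))
        take = min(empty_sample_target, len(empties))
        if take:
            chosen = rng.choice(len(empties), size=take, replace=False)
            for j in sorted(int(c) for c in chosen):
                items.append(ReviewItem(empties[j], dep_id, "empty-sample"))
    return ReviewPlan(tuple(items))
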