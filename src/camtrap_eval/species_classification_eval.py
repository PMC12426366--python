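"""Image-level multiclass species-classification evaluation.

For each species s and threshold t, predictions with score < t are removed
(thresholding uses the per-class maximum score within an image) and images
are tallied one-vs-rest:

* TP - images confirmed to contain s whose surviving predicted label set
  includes s;
* FN - images confirmed to contain s whose surviving predicted set does not
  (including images left with no predictions);
* FP - all remaining images predicted to contain s but not confirmed to.

True negatives are not defined.  Precision = TP/(TP+FP), recall = TP/(TP+FN),
F1 = 2PR/(P+R).  Metrics are swept over a threshold grid (default 0.25-1.0 by
0.05), averaged per class over the grid (threshold-averaged metrics), and
macro-averaged over classes with at least a minimum number of training and
test images.  Ordinary least-squares fits relate the per-class averages to
the (log10) number of training images.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np

from ._stats import simple_ols
from .detections_io import PredictedDetection, VerifiedAnnotation, VocabularyError

__all__ = [
    "CLASSIFICATION_THRESHOLD_GRID",
    "ThresholdMetrics",
    "ClassSummary",
    "MacroMetrics",
    "SizeEffectFit",
    "ImageEvalSet",
    "image_score",
    "image_level_tallies",
    "threshold_sweep",
    "average_metrics",
    "macro_average",
    "fit_size_effect",
    "evaluate_classes",
]

#: Default grid 0.25-1.0 by 0.05, built from integer steps so 0.65 and 1.0
#: are exactly representable and inclusive comparisons are stable.
CLASSIFICATION_THRESHOLD_GRID: tuple[float, ...] = tuple(
    i / 100 for i in range(25, 101, 5)
)


@dataclass(frozen=True)
class ThresholdMetrics:
    class_label: str
    threshold: float
    tp: int
    fp: int
    fn: int

    @property
    def precision(self) -> Optional[float]:
        d = self.tp + self.fp
        return self.tp / d if d else None

    @property
    def recall(self) -> Optional[float]:
        d = self.tp + self.fn
        return self.tp / d if d else None

    @property
    def f1(self) -> Optional[float]:
        p, r = self.precision, self.recall
        if p is None or r is None or p + r == 0:
            return None
        return 2 * p * r / (p + r)


@dataclass(frozen=True)
class ClassSummary:
    class_label: str
    average_precision: Optional[float]
    average_recall: Optional[float]
    average_f1: Optional[float]
    n_train_images: Optional[int]  # None when no training-count table is given
    n_test_images: int
    included_in_macro: bool


@dataclass(frozen=True)
class MacroMetrics:
    macro_precision: float
    macro_recall: float
    macro_f1: float
    n_classes: int


@dataclass(frozen=True)
class SizeEffectFit:
    metric: str  # "precision" | "recall" | "f1"
    predictor: str  # "n_train" | "log10_n_train"
    slope: float
    intercept: float
    r_squared: float
    slope_ci_halfwidth: Optional[float]
    n_classes: int


class ImageEvalSet:
    """Per-image prediction scores and truth label sets for fast sweeps.

    ``image_ids`` fixes the evaluation universe: all reviewed test images,
    including confirmed-empty ones (they can contribute false positives).
    """

    def __init__(
        self,
        predictions: Iterable[PredictedDetection],
        truth: Iterable[VerifiedAnnotation],
        image_ids: Optional[Iterable[str]] = None,
    ) -> None:
        self.pred_scores: dict[str, dict[str, float]] = {}
        for det in predictions:
            scores = self.pred_scores.setdefault(det.image_id, {})
            if det.score > scores.get(det.class_label, -1.0):
                scores[det.class_label] = det.score
        self.truth_labels: dict[str, set[str]] = {}
        for ann in truth:
            self.truth_labels.setdefault(ann.image_id, set()).add(ann.class_label)
        if image_ids is None:
            ids = set(self.pred_scores) | set(self.truth_labels)
        else:
            ids = set(image_ids)
            missing = (set(self.pred_scores) | set(self.truth_labels)) - ids
            if missing:
                raise ValueError(
                    f"{len(missing)} image(s) in predictions/truth missing from image_ids"
                )
        self.image_ids: tuple[str, ...] = tuple(sorted(ids))

    def classes(self) -> tuple[str, ...]:
        labels: set[str] = set()
        for s in self.truth_labels.values():
            labels |= s
        for s in self.pred_scores.values():
            labels |= set(s)
        return tuple(sorted(labels))

    def n_test_images(self, class_label: str) -> int:
        return sum(1 for s in self.truth_labels.values() if class_label in s)


def image_score(
    predictions: Iterable[PredictedDetection], class_label: str
) -> Optional[float]:
    """Max confidence among one image's predictions of ``class_label`` (None if none)."""
    best: Optional[float] = None
    for det in predictions:
        if det.class_label == class_label and (best is None or det.score > best):
            best = det.score
    return best


def _tally(evalset: ImageEvalSet, class_label: str, threshold: float,
           *, score_rule: str = "per-class") -> tuple[int, int, int]:
    tp = fp = fn = 0
    for image_id in evalset.image_ids:
        scores = evalset.pred_scores.get(image_id, {})
        if score_rule == "per-class":
            predicted = scores.get(class_label, -1.0) >= threshold
        elif score_rule == "image-max":
            # alternative reading: the whole image's label set survives iff
            # the overall top score clears the threshold
            overall = max(scores.values(), default=-1.0)
            predicted = class_label in scores and overall >= threshold
        else:
            raise ValueError(f"unknown score_rule {score_rule!r}")
        confirmed = class_label in evalset.truth_labels.get(image_id, ())
        if confirmed:
            tp += predicted
            fn += not predicted
        elif predicted:
            fp += 1
    return tp, fp, fn


def image_level_tallies(
    predictions: Iterable[PredictedDetection],
    truth: Iterable[VerifiedAnnotation],
    class_label: str,
    threshold: float,
    image_ids: Optional[Iterable[str]] = None,
    *,
    score_rule: str = "per-class",
) -> tuple[int, int, int]:
    """(TP, FP, FN) for one class at one threshold.

    ``score_rule`` selects how the within-image maximum is applied:
    ``"per-class"`` (default) thresholds each class on its own top score;
    ``"image-max"`` thresholds the whole image on its single top score.
    """
    evalset = ImageEvalSet(predictions, truth, image_ids)
    if class_label not in evalset.classes() and not any(
        class_label in s for s in evalset.truth_labels.values()
    ):
        # evaluating a class never seen anywhere is almost always a typo
        raise VocabularyError(f"class {class_label!r} absent from predictions and truth")
    return _tally(evalset, class_label, threshold, score_rule=score_rule)


def threshold_sweep(
    predictions: Iterable[PredictedDetection],
    truth: Iterable[VerifiedAnnotation],
    class_label: str,
    grid: Sequence[float] = CLASSIFICATION_THRESHOLD_GRID,
    image_ids: Optional[Iterable[str]] = None,
    *,
    score_rule: str = "per-class",
) -> list[ThresholdMetrics]:
    """One :class:`ThresholdMetrics` per grid point (inclusive >= comparisons)."""
    evalset = predictions if isinstance(predictions, ImageEvalSet) else ImageEvalSet(
        predictions, truth, image_ids
    )
    out = []
    for t in grid:
        tp, fp, fn = _tally(evalset, class_label, float(t), score_rule=score_rule)
        out.append(ThresholdMetrics(class_label, float(t), tp, fp, fn))
    return out


def _mean_defined(values: Iterable[Optional[float]], undefined_as_zero: bool
                  ) -> Optional[float]:
    vals = list(values)
    if undefined_as_zero:
        vals = [0.0 if v is None else v for v in vals]
    else:
        vals = [v for v in vals if v is not None]
    return float(np.mean(vals)) if vals else None


def average_metrics(
    sweep: Sequence[ThresholdMetrics],
    n_train_images: Optional[int],
    n_test_images: int,
    *,
    min_class_images: int = 10,
    undefined_as_zero: bool = False,
) -> ClassSummary:
    """Threshold-averaged (unweighted mean over the grid) per-class metrics.

    Grid points where a metric's denominator is zero are omitted from that
    metric's mean by default; ``undefined_as_zero=True`` imputes them as 0
    instead.  A class is excluded from macro-averaging when it has fewer than
    ``min_class_images`` training or test images; an unknown training count
    (``n_train_images=None``) excludes on test-set size only.
    """
    if not sweep:
        raise ValueError("empty sweep")
    label = sweep[0].class_label
    included = (
        n_train_images is None or n_train_images >= min_class_images
    ) and n_test_images >= min_class_images
    return ClassSummary(
        class_label=label,
        average_precision=_mean_defined((m.precision for m in sweep), undefined_as_zero),
        average_recall=_mean_defined((m.recall for m in sweep), undefined_as_zero),
        average_f1=_mean_defined((m.f1 for m in sweep), undefined_as_zero),
        n_train_images=None if n_train_images is None else int(n_train_images),
        n_test_images=int(n_test_images),
        included_in_macro=included,
    )


def macro_average(summaries: Sequence[ClassSummary]) -> MacroMetrics:
    """Unweighted mean of per-class averages over the included classes."""
    included = [s for s in summaries if s.included_in_macro]
    if not included:
        raise ValueError("no classes eligible for macro-averaging")

    def mean_of(attr: str) -> float:
        vals = [getattr(s, attr) for s in included if getattr(s, attr) is not None]
        if not vals:
            raise ValueError(f"all included classes have undefined {attr}")
        return float(np.mean(vals))

    return MacroMetrics(
        macro_precision=mean_of("average_precision"),
        macro_recall=mean_of("average_recall"),
        macro_f1=mean_of("average_f1"),
        n_classes=len(included),
    )


def fit_size_effect(
    summaries: Sequence[ClassSummary],
    *,
    predictors: Sequence[str] = ("n_train", "log10_n_train"),
    metrics: Sequence[str] = ("precision", "recall", "f1"),
) -> list[SizeEffectFit]:
    """OLS fits of threshold-averaged metrics against training-set size.

    One fit per (metric, predictor) pair over the macro-included classes with
    a defined average; 95% CI half-widths on the slope from the t
    distribution with n - 2 degrees of freedom.
    """
    usable = [s for s in summaries
              if s.included_in_macro and s.n_train_images is not None]
    fits: list[SizeEffectFit] = []
    for metric in metrics:
        attr = f"average_{metric}"
        pts = [(s.n_train_images, getattr(s, attr)) for s in usable
               if getattr(s, attr) is not None]
        if len(pts) < 3:
            raise ValueError(f"need >=3 classes with defined {attr}, got {len(pts)}")
        for predictor in predictors:
            if predictor == "n_train":
                x = [float(n) for n, _ in pts]
            elif predictor == "log10_n_train":
                x = [math.log10(n) for n, _ in pts]
            else:
                raise ValueError(f"unknown predictor {predictor!r}")
            res = simple_ols(x, [y for _, y in pts])
            fits.append(
                SizeEffectFit(metric, predictor, res.slope, res.intercept,
                              res.r_squared, res.slope_ci_halfwidth, res.n)
            )
    return fits


def evaluate_classes(
    predictions: Iterable[PredictedDetection],
    truth: Iterable[VerifiedAnnotation],
    train_counts: Optional[Mapping[str, int]],
    image_ids: Optional[Iterable[str]] = None,
    *,
    classes: Optional[Sequence[str]] = None,
    grid: Sequence[float] = CLASSIFICATION_THRESHOLD_GRID,
    min_class_images: int = 10,
    undefined_as_zero: bool = False,
    score_rule: str = "per-class",
) -> tuple[list[ThresholdMetrics], list[ClassSummary], MacroMetrics]:
    """Full per-class sweep, per-class summaries, and macro averages.

    ``classes`` defaults to every label seen in predictions or truth;
    ``train_counts`` maps class label to its number of training images
    (labels missing from the table count as 0 and are excluded from macro).
    Pass ``train_counts=None`` when no training-count table exists: classes
    are then excluded on test-set size only.
    """
    evalset = ImageEvalSet(predictions, truth, image_ids)
    labels = tuple(classes) if classes is not None else evalset.classes()
    all_metrics: list[ThresholdMetrics] = []
    summaries: list[ClassSummary] = []
    for label in labels:
        sweep = threshold_sweep(evalset, (), label, grid, score_rule=score_rule)
        all_metrics.extend(sweep)
        summaries.append(
            average_metrics(
                sweep,
                None if train_counts is None else int(train_counts.get(label, 0)),
                evalset.n_test_images(label),
                min_class_images=min_class_images,
                undefined_as_zero=undefined_as_zero,
            )
        )
    return all_metrics, summaries, macro_average(summaries)
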