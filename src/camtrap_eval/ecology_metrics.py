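"""Ecological evaluation surface: species richness concordance and count bias.

Species richness (the number of distinct species detected at a station) is
computed twice - from verified annotations and from model predictions at a
score threshold - and the two are compared by ordinary least squares with
predicted richness as the response.  Per-station bias is predicted minus
observed richness.

Per-image animal counts are compared on true-positive images with a single
true species only.  Three models are fitted over species classes:

* difference - cell means of ``count_true - count_pred``;
* ratio - cell means of ``count_pred / count_true`` (a coefficient of 0.78
  is a 22% mean undercount);
* Poisson GLM - ``count_true ~ exp(a_i + b_i * ln(count_pred))`` with a
  per-class intercept and slope (log link), fitted by IRLS.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import statsmodels.api as sm
from scipy import stats

from ._stats import simple_ols
from .detections_io import ImageRecord, PredictedDetection, VerifiedAnnotation

__all__ = [
    "RICHNESS_THRESHOLD_GRID",
    "DEFAULT_EXCLUDED_LABELS",
    "RichnessFit",
    "CountRecord",
    "CoefEstimate",
    "CountModelFit",
    "site_richness",
    "richness_concordance",
    "extract_count_records",
    "fit_count_difference",
    "fit_count_ratio",
    "fit_count_glm",
]

#: Default richness threshold grid: 0.25 to 0.95 by 0.10.
RICHNESS_THRESHOLD_GRID: tuple[float, ...] = tuple(i / 100 for i in range(25, 96, 10))

#: Labels excluded from richness by default (non-species classes).
DEFAULT_EXCLUDED_LABELS: frozenset[str] = frozenset({"human", "vehicle", "unknown"})


@dataclass(frozen=True)
class RichnessFit:
    """OLS fit of predicted on observed richness plus additive bias summary."""

    threshold: Optional[float]
    slope: float
    intercept: float
    r_squared: float
    mean_bias: float
    sd_bias: float
    n_stations: int


@dataclass(frozen=True)
class CountRecord:
    image_id: str
    class_label: str
    count_true: int
    count_pred: int


@dataclass(frozen=True)
class CoefEstimate:
    value: float
    ci_halfwidth: Optional[float]


@dataclass(frozen=True)
class CountModelFit:
    model_form: str  # "difference" | "ratio" | "poisson_glm"
    coefficients: dict[str, CoefEstimate]
    # GLM only: per-class slopes on ln(count_pred) and the residual deviance
    slopes: Optional[dict[str, CoefEstimate]] = None
    deviance: Optional[float] = None

    def predict_true_count(self, class_label: str, count_pred: float) -> float:
        """GLM prediction exp(a_i + b_i ln(count_pred)) for class i."""
        if self.model_form != "poisson_glm" or self.slopes is None:
            raise ValueError("predict_true_count requires a poisson_glm fit")
        a = self.coefficients[class_label].value
        b = self.slopes[class_label].value
        return math.exp(a + b * math.log(count_pred))


def site_richness(
    records: Iterable,
    manifest: Sequence[ImageRecord],
    *,
    threshold: Optional[float] = None,
    excluded_labels: frozenset[str] = DEFAULT_EXCLUDED_LABELS,
) -> dict[str, int]:
    """Distinct species per station from annotations or thresholded predictions.

    ``records`` may be verified annotations (``threshold`` must be None) or
    predictions (``threshold`` required; detections with score < threshold are
    dropped).  Every manifest station is present in the result, with 0 for
    stations without qualifying detections.
    """
    station_of: dict[str, str] = {r.image_id: r.station_id for r in manifest}
    found: dict[str, set[str]] = {r.station_id: set() for r in manifest}
    for rec in records:
        if rec.image_id not in station_of:
            raise ValueError(f"image {rec.image_id!r} missing from manifest")
        if isinstance(rec, PredictedDetection):
            if threshold is None:
                raise ValueError("a threshold is required for predicted richness")
            if rec.score < threshold:
                continue
        elif isinstance(rec, VerifiedAnnotation):
            if threshold is not None:
                raise ValueError("verified richness ignores thresholds; pass threshold=None")
        if rec.class_label in excluded_labels:
            continue
        found[station_of[rec.image_id]].add(rec.class_label)
    return {st: len(sp) for st, sp in sorted(found.items())}


def richness_concordance(
    observed: Mapping[str, int],
    predicted: Mapping[str, int],
    threshold: Optional[float] = None,
) -> RichnessFit:
    """OLS of predicted richness on observed richness over stations.

    Requires the same station set on both sides, at least 3 stations, and
    nonzero variance in observed richness.  Bias is predicted - observed
    (additive); its SD is the sample standard deviation over stations.
    """
    if set(observed) != set(predicted):
        raise ValueError("observed and predicted cover different station sets")
    stations = sorted(observed)
    if len(stations) < 3:
        raise ValueError("need at least 3 stations")
    obs = np.array([observed[s] for s in stations], dtype=float)
    pred = np.array([predicted[s] for s in stations], dtype=float)
    res = simple_ols(obs, pred)
    bias = pred - obs
    sd = float(np.std(bias, ddof=1)) if len(stations) > 1 else 0.0
    return RichnessFit(
        threshold, res.slope, res.intercept, res.r_squared,
        float(bias.mean()), sd, len(stations),
    )


def extract_count_records(
    predictions: Iterable[PredictedDetection],
    truth: Iterable[VerifiedAnnotation],
    threshold: float,
) -> list[CountRecord]:
    """Count comparison records from single-species true-positive images.

    An image qualifies when its truth holds exactly one species and at least
    one surviving (score >= threshold) prediction carries that species.
    ``count_pred`` is the number of surviving predicted boxes of the true
    species only; boxes of other labels on the image are ignored.
    """
    truth_by_image: dict[str, list[VerifiedAnnotation]] = {}
    for ann in truth:
        truth_by_image.setdefault(ann.image_id, []).append(ann)
    surviving: dict[tuple[str, str], int] = {}
    for det in predictions:
        if det.score >= threshold:
            key = (det.image_id, det.class_label)
            surviving[key] = surviving.get(key, 0) + 1
    records: list[CountRecord] = []
    for image_id in sorted(truth_by_image):
        anns = truth_by_image[image_id]
        if len(anns) != 1:
            continue  # multi-species images are excluded from count models
        ann = anns[0]
        n_pred = surviving.get((image_id, ann.class_label), 0)
        if n_pred == 0:
            continue  # not a true-positive image at this threshold
        records.append(CountRecord(image_id, ann.class_label, ann.count, n_pred))
    return records


def _cell_means(
    records: Sequence[CountRecord], response: str
) -> dict[str, CoefEstimate]:
    """Cell-means fit: per-class mean response with 95% CIs from pooled variance."""
    if not records:
        raise ValueError("no count records")
    by_class: dict[str, list[float]] = {}
    for r in records:
        if response == "difference":
            y = float(r.count_true - r.count_pred)
        elif response == "ratio":
            y = r.count_pred / r.count_true
        else:
            raise ValueError(response)
        by_class.setdefault(r.class_label, []).append(y)
    means = {c: float(np.mean(v)) for c, v in by_class.items()}
    n_total = sum(len(v) for v in by_class.values())
    df = n_total - len(by_class)
    pooled = None
    if df > 0:
        rss = sum(
            float(np.sum((np.asarray(v) - means[c]) ** 2)) for c, v in by_class.items()
        )
        pooled = rss / df
    out: dict[str, CoefEstimate] = {}
    for c in sorted(by_class):
        ci = None
        if pooled is not None and len(by_class[c]) > 1:
            ci = float(stats.t.ppf(0.975, df) * math.sqrt(pooled / len(by_class[c])))
        out[c] = CoefEstimate(means[c], ci)
    return out


def fit_count_difference(records: Sequence[CountRecord]) -> CountModelFit:
    """Per-class mean of ``count_true - count_pred`` (additive undercount)."""
    return CountModelFit("difference", _cell_means(records, "difference"))


def fit_count_ratio(records: Sequence[CountRecord]) -> CountModelFit:
    """Per-class mean of ``count_pred / count_true`` (proportional recovery)."""
    return CountModelFit("ratio", _cell_means(records, "ratio"))


def fit_count_glm(
    records: Sequence[CountRecord],
    *,
    tol: float = 1e-8,
    max_iter: int = 200,
) -> CountModelFit:
    """Poisson GLM ``count_true ~ exp(a_i + b_i ln(count_pred))``.

    Nested parameterization: one intercept and one slope per class, so the
    per-class prediction curve is directly ``exp(a_i + b_i ln x)``.  Each
    class needs at least two distinct predicted counts for its slope to be
    estimable.  Fitted by iteratively reweighted least squares (statsmodels)
    to relative tolerance ``tol``; 95% CIs are Wald intervals.
    """
    if not records:
        raise ValueError("no count records")
    classes = sorted({r.class_label for r in records})
    for c in classes:
        preds = {r.count_pred for r in records if r.class_label == c}
        if len(preds) < 2:
            raise ValueError(
                f"class {c!r} has a single distinct predicted count; slope inestimable"
            )
    k = len(classes)
    idx = {c: i for i, c in enumerate(classes)}
    n = len(records)
    X = np.zeros((n, 2 * k))
    y = np.zeros(n)
    for row, r in enumerate(records):
        i = idx[r.class_label]
        X[row, i] = 1.0
        X[row, k + i] = math.log(r.count_pred)
        y[row] = r.count_true
    model = sm.GLM(y, X, family=sm.families.Poisson())
    result = model.fit(maxiter=max_iter, tol=tol)
    if not getattr(result, "converged", True):
        raise RuntimeError("Poisson GLM did not converge")
    z = stats.norm.ppf(0.975)
    params, bse = np.asarray(result.params), np.asarray(result.bse)
    intercepts = {
        c: CoefEstimate(float(params[idx[c]]), float(z * bse[idx[c]])) for c in classes
    }
    slopes = {
        c: CoefEstimate(float(params[k + idx[c]]), float(z * bse[k + idx[c]]))
        for c in classes
    }
    return CountModelFit(
        "poisson_glm", intercepts, slopes=slopes, deviance=float(result.deviance)
    )
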