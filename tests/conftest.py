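"""Shared fixtures and independent brute-force oracles.

The oracle functions here deliberately re-derive metrics by naive enumeration
over raw prediction/annotation lists, independent of the package's tallying
code paths, so equivalence tests are meaningful.
"""

from __future__ import annotations

import numpy as np
import pytest

from camtrap_eval.detections_io import (
    ClassVocabulary,
    ImageRecord,
    PredictedDetection,
    VerifiedAnnotation,
)


# ---------------------------------------------------------------------------
# brute-force oracles


def brute_class_tallies(predictions, truth, images, class_label, threshold):
    """Naive one-vs-rest image tallies: loop every image, no precomputation."""
    tp = fp = fn = 0
    for img in images:
        surviving = {
            p.class_label for p in predictions
            if p.image_id == img and p.score >= threshold
        }
        confirmed = any(
            a.image_id == img and a.class_label == class_label for a in truth
        )
        predicted = class_label in surviving
        if confirmed and predicted:
            tp += 1
        elif confirmed:
            fn += 1
        elif predicted:
            fp += 1
    return tp, fp, fn


def brute_binary_confusion(predictions, truth, images, threshold):
    """Naive animal/empty confusion: every class counts as animal."""
    tp = fp = fn = tn = 0
    for img in images:
        predicted = any(
            p.image_id == img and p.score >= threshold for p in predictions
        )
        has_animal = any(a.image_id == img for a in truth)
        if has_animal:
            tp += predicted
            fn += not predicted
        else:
            fp += predicted
            tn += not predicted
    return tp, fp, fn, tn


# ---------------------------------------------------------------------------
# random instance generation


def random_instance(rng, max_images=50, max_classes=5, max_preds=3):
    """A small random evaluation problem with a random score grid."""
    n_images = int(rng.integers(1, max_images + 1))
    n_classes = int(rng.integers(1, max_classes + 1))
    classes = [f"c{i}" for i in range(n_classes)]
    images = [f"img{i:03d}" for i in range(n_images)]
    truth, predictions = [], []
    for img in images:
        k = int(rng.integers(0, min(2, n_classes) + 1))
        for cls in rng.choice(classes, size=k, replace=False):
            truth.append(VerifiedAnnotation(img, str(cls), int(rng.integers(1, 4))))
        for _ in range(int(rng.integers(0, max_preds + 1))):
            cls = classes[int(rng.integers(0, n_classes))]
            score = int(rng.integers(0, 101)) / 100
            predictions.append(PredictedDetection(img, cls, score))
    n_thresh = int(rng.integers(2, 7))
    grid = sorted({int(v) / 100 for v in rng.integers(0, 101, size=n_thresh)})
    if len(grid) < 2:
        grid = [0.0, 0.5]
    return images, classes, truth, predictions, grid


def manifest_for(images, deployment="d0", station="s0"):
    return [ImageRecord(img, station, deployment) for img in images]


# ---------------------------------------------------------------------------
# fixtures


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def animal_vocab():
    return ClassVocabulary.from_labels(
        ["baboon", "bushbuck", "elephant", "human", "vehicle"]
    )
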