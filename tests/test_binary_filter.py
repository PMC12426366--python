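"""Binary (animal vs. empty) filtering: sweeps, agreement, review planning."""

import numpy as np
import pytest

from conftest import brute_binary_confusion, manifest_for, random_instance

from camtrap_eval.binary_filter_eval import (
    BINARY_THRESHOLD_GRID,
    BinaryImageRecord,
    binary_confusion_sweep,
    collapse_to_binary,
    compare_detectors,
    plan_review,
)
from camtrap_eval.detections_io import (
    ClassVocabulary,
    ImageRecord,
    PredictedDetection,
    VerifiedAnnotation,
)


def records_from_scores(animal_scores, empty_scores):
    recs = []
    for i, s in enumerate(animal_scores):
        recs.append(BinaryImageRecord(f"a{i}", "animal", s))
    for i, s in enumerate(empty_scores):
        recs.append(BinaryImageRecord(f"e{i}", "empty", s))
    return recs


class TestBinaryConfusionSweep:
    def test_hand_enumerated_example(self):
        # 4 animal images (scores 0.9, 0.5, 0.3, none), 6 empty images
        # (scores 0.4, 0.8, none x4)
        recs = records_from_scores([0.9, 0.5, 0.3, None],
                                   [0.4, 0.8, None, None, None, None])
        by_t = {c.threshold: c for c in binary_confusion_sweep(recs, [0.25, 0.6])}
        c = by_t[0.25]
        assert (c.tp, c.fn, c.fp, c.tn) == (3, 1, 2, 4)
        assert c.sensitivity == pytest.approx(0.75)
        assert c.specificity == pytest.approx(2 / 3, abs=1e-4)
        c = by_t[0.6]
        assert (c.tp, c.fn, c.fp, c.tn) == (1, 3, 1, 5)
        assert c.sensitivity == pytest.approx(0.25)
        assert c.specificity == pytest.approx(5 / 6, abs=1e-4)

    def test_perfect_detector_all_thresholds(self):
        recs = records_from_scores([1.0] * 5, [None] * 5)
        for c in binary_confusion_sweep(recs, BINARY_THRESHOLD_GRID):
            assert c.sensitivity == 1.0 and c.specificity == 1.0

    def test_no_predictions_at_all(self):
        recs = records_from_scores([None] * 3, [None] * 4)
        for c in binary_confusion_sweep(recs, BINARY_THRESHOLD_GRID):
            assert c.sensitivity == 0.0 and c.specificity == 1.0

    def test_empty_record_set_is_an_error(self):
        with pytest.raises(ValueError, match="no binary"):
            binary_confusion_sweep([], BINARY_THRESHOLD_GRID)

    def test_bad_grids_rejected(self):
        recs = records_from_scores([0.5], [None])
        with pytest.raises(ValueError):
            binary_confusion_sweep(recs, [0.5, 0.3])
        with pytest.raises(ValueError):
            binary_confusion_sweep(recs, [0.5, 1.3])

    def test_monotonicity_and_conservation_random(self, rng):
        for _ in range(30):
            scores = [
                None if rng.random() < 0.3 else int(rng.integers(0, 101)) / 100
                for _ in range(int(rng.integers(2, 40)))
            ]
            states = ["animal" if rng.random() < 0.5 else "empty" for _ in scores]
            recs = [BinaryImageRecord(f"i{k}", st, sc)
                    for k, (st, sc) in enumerate(zip(states, scores))]
            sweep = binary_confusion_sweep(recs, BINARY_THRESHOLD_GRID)
            for a, b in zip(sweep, sweep[1:]):
                assert b.tp <= a.tp and b.tn >= a.tn
            assert len({c.tp + c.fn for c in sweep}) == 1
            assert len({c.fp + c.tn for c in sweep}) == 1


class TestCollapseToBinary:
    def test_max_over_animal_predictions(self, animal_vocab):
        preds = [PredictedDetection("i1", "baboon", 0.4),
                 PredictedDetection("i1", "bushbuck", 0.9)]
        truth = [VerifiedAnnotation("i1", "baboon", 1)]
        recs = collapse_to_binary(preds, truth, manifest_for(["i1"]), animal_vocab)
        assert recs == [BinaryImageRecord("i1", "animal", 0.9)]

    def test_confirmed_empty_image(self, animal_vocab):
        recs = collapse_to_binary([], [], manifest_for(["i1"]), animal_vocab)
        assert recs == [BinaryImageRecord("i1", "empty", None)]

    def test_human_only_truth_excluded(self, animal_vocab):
        truth = [VerifiedAnnotation("i1", "human", 1)]
        recs = collapse_to_binary([], truth, manifest_for(["i1"]), animal_vocab)
        assert recs == []

    def test_multi_class_truth_excluded(self, animal_vocab):
        truth = [VerifiedAnnotation("i1", "baboon", 1),
                 VerifiedAnnotation("i1", "elephant", 2)]
        recs = collapse_to_binary([], truth, manifest_for(["i1"]), animal_vocab)
        assert recs == []

    def test_human_prediction_on_empty_image_excluded(self, animal_vocab):
        preds = [PredictedDetection("i1", "human", 0.99)]
        recs = collapse_to_binary(preds, [], manifest_for(["i1"]), animal_vocab)
        assert recs == []

    def test_keep_nonanimal_switch_retains_as_empty(self, animal_vocab):
        truth = [VerifiedAnnotation("i1", "human", 1)]
        recs = collapse_to_binary([], truth, manifest_for(["i1"]), animal_vocab,
                                  keep_nonanimal=True)
        assert recs == [BinaryImageRecord("i1", "empty", None)]

    def test_unreviewed_images_skipped(self, animal_vocab):
        manifest = [ImageRecord("i1", "s0", "d0", reviewed=False),
                    ImageRecord("i2", "s0", "d0", reviewed=True)]
        recs = collapse_to_binary([], [], manifest, animal_vocab)
        assert [r.image_id for r in recs] == ["i2"]

    def test_human_score_never_counts_as_animal(self, animal_vocab):
        preds = [PredictedDetection("i1", "human", 0.99),
                 PredictedDetection("i1", "baboon", 0.3)]
        truth = [VerifiedAnnotation("i1", "baboon", 1)]
        recs = collapse_to_binary(preds, truth, manifest_for(["i1"]), animal_vocab)
        assert recs[0].max_animal_score == 0.3


class TestBruteForceEquivalence:
    def test_sweep_matches_naive_enumeration(self, rng):
        vocab_cache = {}
        for _ in range(40):
            images, classes, truth, preds, grid = random_instance(rng)
            vocab = vocab_cache.setdefault(
                len(classes), ClassVocabulary.from_labels([f"c{i}" for i in range(5)])
            )
            recs = collapse_to_binary(preds, truth, manifest_for(images), vocab,
                                      keep_nonanimal=True)
            # restrict oracle to single-true-class or empty images kept above
            sweep = binary_confusion_sweep(recs, grid) if recs else []
            kept = {r.image_id for r in recs}
            for c in sweep:
                exp = brute_binary_confusion(
                    [p for p in preds if p.image_id in kept],
                    [a for a in truth if a.image_id in kept],
                    sorted(kept), c.threshold,
                )
                assert (c.tp, c.fp, c.fn, c.tn) == exp


class TestCompareDetectors:
    def test_identical_records_have_no_disagreement(self):
        recs = records_from_scores([0.9, 0.4], [0.2, None])
        table = compare_detectors(recs, recs, 0.5)
        assert table.cell(True, False) == 0 and table.cell(False, True) == 0
        assert table.total == 4

    def test_opposite_detectors(self):
        a = [BinaryImageRecord(f"i{k}", "animal", 1.0) for k in range(10)]
        b = [BinaryImageRecord(f"i{k}", "animal", None) for k in range(10)]
        table = compare_detectors(a, b, 0.25)
        assert table.cell(True, False) == 10

    def test_three_image_hand_enumeration(self):
        a = [BinaryImageRecord("i1", "animal", 0.9),
             BinaryImageRecord("i2", "animal", 0.2),
             BinaryImageRecord("i3", "empty", 0.9)]
        b = [BinaryImageRecord("i1", "animal", 0.9),
             BinaryImageRecord("i2", "animal", 0.9),
             BinaryImageRecord("i3", "empty", None)]
        table = compare_detectors(a, b, 0.5)
        assert table.cell(True, True) == 1
        assert table.cell(True, False) == 1
        assert table.cell(False, True) == 1
        assert table.cell(False, False) == 0

    def test_mismatched_image_sets_rejected(self):
        a = [BinaryImageRecord("i1", "animal", 0.9)]
        b = [BinaryImageRecord("i2", "animal", 0.9)]
        with pytest.raises(ValueError, match="2 image"):
            compare_detectors(a, b, 0.5)


class TestPlanReview:
    def make_deployment(self, n_empty, animal_scores, vocab, dep="d0"):
        manifest, preds = [], []
        for i in range(n_empty):
            manifest.append(ImageRecord(f"{dep}_e{i:05d}", "s0", dep))
        for i, s in enumerate(animal_scores):
            img = f"{dep}_a{i:05d}"
            manifest.append(ImageRecord(img, "s0", dep))
            preds.append(PredictedDetection(img, "baboon", s))
        return manifest, preds

    def test_empty_sample_capped_at_target(self, animal_vocab):
        manifest, preds = self.make_deployment(500, [], animal_vocab)
        plan = plan_review(preds, manifest, animal_vocab, seed=1)
        assert sum(1 for it in plan.items if it.reason == "empty-sample") == 100

    def test_small_deployment_takes_all_empties(self, animal_vocab):
        manifest, preds = self.make_deployment(60, [], animal_vocab)
        plan = plan_review(preds, manifest, animal_vocab, seed=1)
        assert sum(1 for it in plan.items if it.reason == "empty-sample") == 60

    def test_overflow_stratum_bin_sampling(self, animal_vocab, rng):
        scores = [float(s) for s in rng.uniform(0.25, 1.0, size=3000)]
        manifest, preds = self.make_deployment(0, scores, animal_vocab)
        plan = plan_review(preds, manifest, animal_vocab,
                           overflow_trigger=2000, bin_sample_target=50, seed=2)
        binned = [it for it in plan.items if it.reason == "bin-sample"]
        assert len(binned) <= 200
        # every nonempty bin contributes its full 50 (3000 uniform scores
        # guarantee >50 per bin)
        by_bin = {}
        score_of = {p.image_id: p.score for p in preds}
        for it in binned:
            s = score_of[it.image_id]
            b = 0 if s <= 0.25 else 1 if s <= 0.5 else 2 if s <= 0.75 else 3
            by_bin[b] = by_bin.get(b, 0) + 1
        assert all(v == 50 for b, v in by_bin.items() if b > 0)

    def test_below_trigger_takes_every_animal_prediction(self, animal_vocab):
        manifest, preds = self.make_deployment(5, [0.3, 0.9, 0.1], animal_vocab)
        plan = plan_review(preds, manifest, animal_vocab, seed=3)
        taken = {it.image_id for it in plan.items if it.reason == "animal-prediction"}
        # the 0.1-score image falls below the floor and counts as predicted-empty
        assert len(taken) == 2

    def test_no_duplicates_and_ids_within_deployment(self, animal_vocab):
        manifest, preds = self.make_deployment(30, [0.5] * 10, animal_vocab)
        plan = plan_review(preds, manifest, animal_vocab, seed=4)
        ids = [it.image_id for it in plan.items]
        assert len(ids) == len(set(ids))
        valid = {r.image_id for r in manifest}
        assert set(ids) <= valid

    def test_deterministic_under_seed(self, animal_vocab):
        manifest, preds = self.make_deployment(300, [0.5] * 10, animal_vocab)
        p1 = plan_review(preds, manifest, animal_vocab, seed=5)
        p2 = plan_review(preds, manifest, animal_vocab, seed=5)
        assert p1 == p2
        p3 = plan_review(preds, manifest, animal_vocab, seed=6)
        assert {i.image_id for i in p1.items} != {i.image_id for i in p3.items}
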