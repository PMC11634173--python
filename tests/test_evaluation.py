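"""Zone extraction, pixel/object metrics, overlays, evaluation suite."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from icgfa.containers import EXPERT, GOOD, POOR, ContractError
from icgfa.evaluation import (
    evaluate_suite,
    extract_expert_zone,
    object_hit,
    pixel_metrics,
    render_overlay,
)


def zone_oracle(labels, min_run):
    """Exhaustive enumeration of all expert runs."""
    runs = []
    i = 0
    labels = list(labels)
    while i < len(labels):
        if labels[i] == EXPERT:
            j = i
            while j < len(labels) and labels[j] == EXPERT:
                j += 1
            runs.append((i, j))
            i = j
        else:
            i += 1
    runs = [r for r in runs if r[1] - r[0] >= min_run]
    if not runs:
        return None
    return max(runs, key=lambda r: (r[1] - r[0], -r[0]))


class TestExtractExpertZone:
    def test_all_good_labels_yield_no_prediction(self):
        zone = extract_expert_zone(np.full(40, GOOD))
        assert zone.no_prediction and zone.expert_zone is None

    def test_longest_run_wins(self):
        labels = np.full(40, GOOD)
        labels[3:7] = EXPERT       # length 4
        labels[20:29] = EXPERT     # length 9
        zone = extract_expert_zone(labels)
        assert zone.expert_zone == (20, 29)

    def test_single_run_returned_verbatim(self):
        labels = np.full(60, POOR)
        labels[35:47] = EXPERT
        assert extract_expert_zone(labels).expert_zone == (35, 47)

    def test_short_run_below_min_run_is_no_prediction(self):
        labels = np.full(30, GOOD)
        labels[10:14] = EXPERT
        assert extract_expert_zone(labels, min_run=6).no_prediction

    def test_tie_goes_to_proximal_run(self):
        labels = np.full(40, GOOD)
        labels[5:12] = EXPERT
        labels[20:27] = EXPERT
        assert extract_expert_zone(labels).expert_zone == (5, 12)

    def test_matches_enumeration_oracle_on_random_sequences(self):
        rng = np.random.default_rng(0)
        for _ in range(300):
            labels = rng.integers(0, 3, size=rng.integers(1, 60))
            for min_run in (1, 3, 6):
                zone = extract_expert_zone(labels, min_run)
                expected = zone_oracle(labels, min_run)
                assert zone.expert_zone == expected

    def test_empty_labels_rejected(self):
        with pytest.raises(ContractError):
            extract_expert_zone(np.array([]))


class TestPixelMetrics:
    def test_perfect_prediction_scores_one_everywhere(self):
        truth = np.array([GOOD] * 10 + [EXPERT] * 12 + [POOR] * 10)
        m = pixel_metrics(truth, truth)
        for key in ("accuracy", "precision", "recall", "specificity",
                    "f1", "dice"):
            assert m[key] == 1.0

    def test_disjoint_expert_sets_score_zero_overlap(self):
        pred = np.array([EXPERT] * 5 + [GOOD] * 5)
        truth = np.array([GOOD] * 5 + [EXPERT] * 5)
        m = pixel_metrics(pred, truth)
        assert m["dice"] == 0.0 and m["recall"] == 0.0

    def test_half_overlap_dice(self):
        # P = [0, 12), G = [6, 18): |P ∩ G| = 6, DICE = 12/24
        pred = np.where(np.arange(30) < 12, EXPERT, GOOD)
        truth = np.where((np.arange(30) >= 6) & (np.arange(30) < 18),
                         EXPERT, GOOD)
        assert pixel_metrics(pred, truth)["dice"] == pytest.approx(0.5)

    def test_both_empty_reported_vacuous_one(self):
        pred = np.full(20, GOOD)
        truth = np.full(20, POOR)
        m = pixel_metrics(pred, truth)
        assert m["vacuous"] and m["dice"] == 1.0 and m["precision"] == 1.0

    def test_matches_bruteforce_confusion_recount(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            n = rng.integers(5, 80)
            pred = rng.integers(0, 3, n)
            truth = rng.integers(0, 3, n)
            m = pixel_metrics(pred, truth)
            tp = sum(1 for p, g in zip(pred, truth)
                     if p == EXPERT and g == EXPERT)
            fp = sum(1 for p, g in zip(pred, truth)
                     if p == EXPERT and g != EXPERT)
            fn = sum(1 for p, g in zip(pred, truth)
                     if p != EXPERT and g == EXPERT)
            tn = n - tp - fp - fn
            assert (m["tp"], m["fp"], m["fn"], m["tn"]) == (tp, fp, fn, tn)
            assert m["accuracy"] == pytest.approx((tp + tn) / n)
            if tp + fp + fn:
                assert m["dice"] == pytest.approx(2 * tp / (2 * tp + fp + fn))

    def test_agrees_with_sklearn(self):
        from sklearn.metrics import f1_score, precision_score, recall_score

        rng = np.random.default_rng(5)
        pred = rng.integers(0, 3, 200)
        truth = rng.integers(0, 3, 200)
        m = pixel_metrics(pred, truth)
        assert m["precision"] == pytest.approx(
            precision_score(truth == EXPERT, pred == EXPERT))
        assert m["recall"] == pytest.approx(
            recall_score(truth == EXPERT, pred == EXPERT))
        assert m["f1"] == pytest.approx(
            f1_score(truth == EXPERT, pred == EXPERT))

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(st.lists(st.tuples(st.integers(0, 2), st.integers(0, 2)),
                    min_size=1, max_size=60))
    def test_f1_equals_dice_and_bounds(self, pairs):
        pred = np.array([p for p, _ in pairs])
        truth = np.array([g for _, g in pairs])
        m = pixel_metrics(pred, truth)
        assert m["f1"] == m["dice"]
        for key in ("accuracy", "precision", "recall", "specificity",
                    "f1", "dice"):
            assert 0.0 <= m[key] <= 1.0
        # specificity + false positive rate = 1 whenever defined
        fp, tn = m["fp"], m["tn"]
        if fp + tn:
            assert m["specificity"] + fp / (fp + tn) == pytest.approx(1.0)

    def test_dice_monotone_as_zone_grows_into_truth(self):
        truth = np.where((np.arange(60) >= 20) & (np.arange(60) < 40),
                         EXPERT, GOOD)
        last = 0.0
        for width in range(1, 21):
            pred = np.where((np.arange(60) >= 20)
                            & (np.arange(60) < 20 + width), EXPERT, GOOD)
            d = pixel_metrics(pred, truth)["dice"]
            assert d >= last
            last = d

    def test_length_mismatch_rejected(self):
        with pytest.raises(ContractError):
            pixel_metrics(np.zeros(3), np.zeros(4))


class TestObjectHit:
    def test_center_inside_zone(self):
        zone = extract_expert_zone(
            np.where((np.arange(60) >= 35) & (np.arange(60) < 47),
                     EXPERT, GOOD))
        assert object_hit(zone, (34, 46))   # centre 40 in [35, 47)

    def test_no_prediction_is_never_a_hit(self):
        zone = extract_expert_zone(np.full(30, GOOD))
        assert not object_hit(zone, (10, 22))

    def test_center_exactly_at_zone_end_misses(self):
        labels = np.full(60, GOOD)
        labels[10:20] = EXPERT
        zone = extract_expert_zone(labels)
        # band centred exactly on the half-open end coordinate 20
        assert not object_hit(zone, (14, 26))
        assert object_hit(zone, (13, 25))

    def test_overlap_rule(self):
        labels = np.full(60, GOOD)
        labels[10:20] = EXPERT
        zone = extract_expert_zone(labels)
        assert object_hit(zone, (18, 30), rule="overlap")
        assert not object_hit(zone, (20, 32), rule="overlap")


class TestRenderOverlay:
    def _frame(self):
        return np.full((60, 80, 3), 100, dtype=np.uint8)

    def test_all_good_draws_red_only(self):
        coords = np.stack([np.full(10, 5), np.arange(10)], axis=1)
        out = render_overlay(self._frame(), coords, np.full(10, GOOD),
                             alpha=1.0)
        tinted = out[25, 0:50]
        assert np.all(tinted[:, 0] == 255) and np.all(tinted[:, 1] == 0)

    def test_expert_modules_tinted_green(self):
        coords = np.stack([np.full(10, 5), np.arange(10)], axis=1)
        labels = np.full(10, GOOD)
        labels[4:8] = EXPERT
        out = render_overlay(self._frame(), coords, labels, alpha=1.0)
        assert np.all(out[25, 20:40, 1] == 255)
        assert np.all(out[25, 20:40, 0] == 0)

    def test_zero_alpha_returns_input(self):
        coords = np.stack([np.full(10, 5), np.arange(10)], axis=1)
        out = render_overlay(self._frame(), coords, np.full(10, POOR),
                             alpha=0.0)
        assert np.array_equal(out, self._frame())

    def test_no_prediction_suppresses_expert_tint(self):
        coords = np.stack([np.full(10, 5), np.arange(10)], axis=1)
        labels = np.full(10, GOOD)
        labels[4:6] = EXPERT
        zone = extract_expert_zone(labels, min_run=6)
        out = render_overlay(self._frame(), coords, labels, zone, alpha=1.0)
        assert np.all(out[25, 20:30, 1] != 255)

    def test_out_of_frame_line_rejected(self):
        from icgfa.containers import GeometryError

        coords = np.array([[100, 3]])
        with pytest.raises(GeometryError):
            render_overlay(self._frame(), coords, np.array([GOOD]))


class TestEvaluateSuite:
    def _line_scenes(self, n, rng):
        from test_models import synthetic_sequences
        from icgfa.containers import GroundTruthAnnotation

        scenes = []
        for s in synthetic_sequences(n, rng):
            idx = np.flatnonzero(s.labels == EXPERT)
            band = (int(s.coords[idx[0], 1]), int(s.coords[idx[-1], 1]) + 1)
            ann = GroundTruthAnnotation(
                line=np.zeros((2, 2)), labels=s.labels,
                stapler_center=(band[0] + band[1]) // 2, stapler_band=band,
                line_cols=s.coords[:, 1])
            scenes.append((s, ann))
        return scenes

    def test_perfect_oracle_scores_one(self):
        rng = np.random.default_rng(0)
        scenes = self._line_scenes(5, rng)
        report = evaluate_suite(lambda s: s.labels, scenes)
        assert report.object_accuracy == 1.0
        assert report.metrics["dice"] == 1.0
        assert len(report.per_case) == 5

    def test_all_poor_predictor_scores_zero(self):
        rng = np.random.default_rng(1)
        scenes = self._line_scenes(4, rng)
        report = evaluate_suite(lambda s: np.full(len(s), POOR), scenes)
        assert report.object_accuracy == 0.0
        assert report.metrics["recall"] == 0.0
        assert report.n_no_prediction == 4

    def test_pooled_metrics_match_recount_from_per_case(self):
        rng = np.random.default_rng(2)
        scenes = self._line_scenes(6, rng)

        def noisy_predictor(s):
            flips = rng.random(len(s)) < 0.2
            return np.where(flips, (s.labels + 1) % 3, s.labels)

        preds = {}

        def recorded(s):
            p = noisy_predictor(s)
            preds[id(s)] = (p, s.labels)
            return p

        report = evaluate_suite(recorded, scenes)
        tp = fp = fn = tn = 0
        for p, g in preds.values():
            tp += int(np.sum((p == EXPERT) & (g == EXPERT)))
            fp += int(np.sum((p == EXPERT) & (g != EXPERT)))
            fn += int(np.sum((p != EXPERT) & (g == EXPERT)))
            tn += int(np.sum((p != EXPERT) & (g != EXPERT)))
        assert report.metrics["tp"] == tp
        assert report.metrics["accuracy"] == pytest.approx(
            (tp + tn) / (tp + fp + fn + tn))
        if tp + fp + fn:
            assert report.metrics["dice"] == pytest.approx(
                2 * tp / (2 * tp + fp + fn))

    def test_empty_scene_list_rejected(self):
        with pytest.raises(ContractError):
            evaluate_suite(lambda s: s.labels, [])
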