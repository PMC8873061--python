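"""Frame metrics and the event-based Ward taxonomy, vs a brute-force oracle."""

import itertools

import numpy as np
import pytest

from sacroseg.core import ClipLabelSequence, ValidationError
from sacroseg.evaluation import (
    Event,
    confusion_matrix,
    extract_events,
    frame_metrics,
    harmonic_f1,
    ward_score,
)
from tests.conftest import random_label_pair


# ---------------------------------------------------------------------------
# independent brute-force oracle: frame-index sets + literal rule table
# ---------------------------------------------------------------------------

def _runs(seq, cls):
    out = []
    for is_cls, group in itertools.groupby(enumerate(seq), key=lambda p: p[1] == cls):
        if is_cls:
            idx = [i for i, _ in group]
            out.append(frozenset(idx))
    return out


def ward_oracle(gt, pred, classes):
    counts = {c: 0 for c in ("C", "D", "F", "M", "FM", "I'", "F'", "M'", "FM'")}
    n_gt = n_pred = 0
    for cls in classes:
        G = _runs(gt, cls)
        P = _runs(pred, cls)
        n_gt += len(G)
        n_pred += len(P)
        partners_of_g = {g: [p for p in P if g & p] for g in G}
        partners_of_p = {p: [g for g in G if g & p] for p in P}
        for g in G:
            ps = partners_of_g[g]
            fragmented = len(ps) > 1
            merged = any(len(partners_of_p[p]) > 1 for p in ps)
            if not ps:
                counts["D"] += 1
            elif fragmented and merged:
                counts["FM"] += 1
            elif fragmented:
                counts["F"] += 1
            elif merged:
                counts["M"] += 1
            else:
                counts["C"] += 1
        for p in P:
            gs = partners_of_p[p]
            merging = len(gs) > 1
            fragmenting = any(len(partners_of_g[g]) > 1 for g in gs)
            if not gs:
                counts["I'"] += 1
            elif merging and fragmenting:
                counts["FM'"] += 1
            elif merging:
                counts["M'"] += 1
            elif fragmenting:
                counts["F'"] += 1
    return counts, n_gt, n_pred


class TestExtractEvents:
    def test_runs_and_gaps(self):
        events = extract_events(np.array([1, 1, 2, 1]), 1)
        assert events == [Event(1, 0, 1), Event(1, 3, 3)]

    def test_absent_class_empty(self):
        assert extract_events(np.array([1, 1]), 4) == []

    def test_full_sequence_single_event(self):
        assert extract_events(np.array([3] * 7), 3) == [Event(3, 0, 6)]


class TestWardScore:
    def test_fragmentation_example(self):
        gt = np.array([1, 1, 1, 1, 2, 2, 2, 2])
        pred = np.array([1, 1, 3, 1, 2, 2, 2, 2])
        s = ward_score(gt, pred)
        assert (s["C"], s["F"], s["F'"], s["I'"]) == (1, 1, 2, 1)
        for cat in ("D", "M", "M'", "FM", "FM'"):
            assert s[cat] == 0
        assert s.event_ratio == pytest.approx(0.5)

    def test_merge_and_deletion_example(self):
        gt = np.array([1, 1, 2, 2, 1, 1])
        pred = np.array([1, 1, 1, 1, 1, 1])
        s = ward_score(gt, pred)
        assert (s["M"], s["M'"], s["D"], s["C"]) == (2, 1, 1, 0)
        assert s.event_ratio == pytest.approx(3.0)

    def test_identity_all_correct(self, rng):
        gt = rng.integers(1, 6, size=80)
        s = ward_score(gt, gt.copy())
        assert s["C"] == s.n_gt_events == s.n_pred_events
        assert s.event_ratio == pytest.approx(1.0)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValidationError, match="length"):
            ward_score(np.array([1, 1]), np.array([1]))

    def test_matches_brute_force_oracle(self, rng):
        """1,000 random pairs: category-for-category oracle equivalence."""
        classes = [1, 2, 3, 4]
        for _ in range(1000):
            gt, pred = random_label_pair(rng)
            s = ward_score(gt, pred, classes=classes)
            oracle_counts, n_gt, n_pred = ward_oracle(gt.tolist(), pred.tolist(),
                                                      classes)
            assert dict(s.counts) == oracle_counts
            assert s.n_gt_events == n_gt == s["C"] + s["D"] + s["F"] + s["M"] + s["FM"]
            assert s.n_pred_events == n_pred == (
                s["C"] + s["I'"] + s["F'"] + s["M'"] + s["FM'"])

    def test_matched_pair_count_symmetric(self, rng):
        """C derived from the prediction side equals the GT-side count."""
        for _ in range(200):
            gt, pred = random_label_pair(rng)
            s = ward_score(gt, pred, classes=[1, 2, 3, 4])
            c_pred_side = s.n_pred_events - (s["I'"] + s["F'"] + s["M'"] + s["FM'"])
            assert c_pred_side == s["C"]

    def test_isolated_insertion_increments_i_prime(self):
        gt = np.array([1] * 10 + [6] * 3 + [2] * 10)
        pred = gt.copy()
        s0 = ward_score(gt, pred)
        pred2 = pred.copy()
        pred2[11] = 3  # spurious event inside the transition gap
        s1 = ward_score(gt, pred2)
        assert s1["I'"] == s0["I'"] + 1
        for cat in ("C", "D", "F", "M", "FM"):
            assert s1[cat] == s0[cat]


class TestFrameMetrics:
    @pytest.mark.parametrize("p,r,f1", [
        (74.6, 78.8, 0.77), (74.9, 71.2, 0.73), (58.5, 68.6, 0.63),
    ])
    def test_harmonic_f1_reproduces_reported_triples(self, p, r, f1):
        assert round(harmonic_f1(p, r) / 100.0, 2) == f1

    def test_perfect_prediction(self, rng):
        gt = np.concatenate([np.full(20, p) for p in range(1, 6)] + [[6, 6, 0]])
        m = frame_metrics(gt, gt.copy())
        assert m.macro_precision == m.macro_recall == m.f1 == 1.0
        assert m.micro_accuracy == 1.0

    def test_transition_excluded_from_macro_average(self):
        gt = np.array([1] * 10 + [6] * 10 + [2] * 10)
        pred = gt.copy()
        pred[10:20] = 1  # all transition clips called phase 1
        m = frame_metrics(gt, pred)
        assert m.macro_recall == pytest.approx(1.0)   # phases themselves perfect
        assert m.macro_precision < 1.0                # phase-1 precision dinged
        assert m.micro_accuracy == pytest.approx(1.0)  # accuracy over phases only

    def test_nonphase_positions_fully_excluded(self):
        gt = np.array([0, 0, 1, 1, 2, 2, 0])
        pred = np.array([3, 4, 1, 1, 2, 2, 5])  # wrong only where gt is non-phase
        m = frame_metrics(gt, pred)
        assert m.micro_accuracy == pytest.approx(1.0)
        assert m.macro_precision == pytest.approx(1.0)

    def test_no_phase_positions_rejected(self):
        with pytest.raises(ValidationError, match="undefined"):
            frame_metrics(np.array([0, 6, 0]), np.array([1, 2, 3]))


class TestConfusionMatrix:
    def test_identity_for_perfect_prediction(self, rng):
        gt = np.concatenate([np.full(10, p) for p in range(1, 6)])
        cm = confusion_matrix(gt, gt.copy())
        assert np.allclose(cm, np.eye(5))

    def test_rows_sum_to_one(self, rng):
        gt = rng.integers(1, 6, size=500)
        pred = rng.integers(1, 6, size=500)
        cm = confusion_matrix(gt, pred)
        assert np.allclose(cm.sum(axis=1), 1.0, atol=1e-9)

    def test_hand_counted_example(self):
        cm = confusion_matrix(np.array([1, 1, 2, 2]), np.array([1, 2, 2, 2]))
        assert np.allclose(cm[0], [0.5, 0.5, 0, 0, 0])
        assert np.allclose(cm[1], [0, 1, 0, 0, 0])
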