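import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import cystseg as cs
from cystseg.evaluation import EvalCounts

from _oracles import pixel_confusion


class TestCountPixels:
    def test_perfect_prediction(self, rng):
        truth = rng.random((12, 12)) > 0.5
        c = cs.count_pixels(truth, truth)
        assert (c.tp, c.fp, c.fn) == (int(truth.sum()), 0, 0)

    def test_disjoint_masks(self):
        a = np.zeros((6, 6), bool)
        b = np.zeros((6, 6), bool)
        a[:2] = True
        b[4:] = True
        c = cs.count_pixels(a, b)
        assert c.tp == 0 and c.fp == 12 and c.fn == 12

    def test_matches_exhaustive_tally(self, rng):
        for _ in range(5):
            pred = rng.random((15, 11)) > 0.6
            truth = rng.random((15, 11)) > 0.6
            c = cs.count_pixels(pred, truth)
            assert (c.tp, c.fp, c.fn) == pixel_confusion(pred, truth)

    def test_area_identities(self, rng):
        pred = rng.random((10, 10)) > 0.5
        truth = rng.random((10, 10)) > 0.5
        c = cs.count_pixels(pred, truth)
        assert c.truth_area == int(truth.sum())
        assert c.pred_area == int(pred.sum())

    def test_shape_mismatch_raises(self):
        with pytest.raises(ValueError):
            cs.count_pixels(np.zeros((3, 3), bool), np.zeros((4, 3), bool))


class TestComputeMetrics:
    def test_published_average_counts(self):
        """Printed per-method pixel averages reproduce hand arithmetic."""
        c = EvalCounts(tp=6370, fp=1358, fn=588)
        m = cs.compute_metrics(c)
        assert m.recall == pytest.approx(100 * 6370 / (6370 + 588), abs=5e-5)
        assert m.precision == pytest.approx(100 * 6370 / (6370 + 1358), abs=5e-5)
        assert m.accuracy == pytest.approx(100 * 6370 / (6370 + 588 + 1358), abs=5e-5)
        p, r = 100 * 6370 / 7728, 100 * 6370 / 6958
        assert m.f1 == pytest.approx(2 * p * r / (p + r), abs=5e-5)
        # consistency: TP + FN reproduces the reported mean truth area
        assert c.truth_area == 6958

    def test_perfect_counts_give_all_hundred(self):
        m = cs.compute_metrics(EvalCounts(tp=42, fp=0, fn=0))
        assert (m.accuracy, m.recall, m.precision, m.f1) == (100, 100, 100, 100)

    def test_zero_tp_gives_zero_metrics(self):
        m = cs.compute_metrics(EvalCounts(tp=0, fp=5, fn=7))
        assert (m.accuracy, m.recall, m.precision, m.f1) == (0, 0, 0, 0)

    def test_undefined_denominators_flagged_not_zeroed(self):
        m = cs.compute_metrics(EvalCounts(tp=0, fp=0, fn=0))
        assert m.accuracy is None and m.recall is None and m.precision is None
        assert set(m.undefined) == {"accuracy", "recall", "precision", "f1"}

    @given(tp=st.integers(1, 500), fp=st.integers(0, 500), fn=st.integers(0, 500))
    def test_jaccard_accuracy_never_exceeds_f1(self, tp, fp, fn):
        m = cs.compute_metrics(EvalCounts(tp, fp, fn))
        assert m.accuracy <= m.f1 + 1e-9
        if fp > 0 and fn > 0:
            assert m.accuracy < min(m.recall, m.precision)


class TestAcceptanceProxy:
    def test_exact_prediction_accepted(self, rng):
        truth = np.zeros((20, 20), bool)
        truth[5:15, 5:15] = True
        assert cs.extraction_accepted(truth, truth)

    def test_empty_prediction_rejected(self):
        truth = np.ones((5, 5), bool)
        assert not cs.extraction_accepted(np.zeros_like(truth), truth)

    def test_disjoint_prediction_rejected(self):
        truth = np.zeros((20, 20), bool)
        truth[:5, :5] = True
        pred = np.zeros_like(truth)
        pred[15:, 15:] = True
        assert not cs.extraction_accepted(pred, truth)

    def test_centroid_containment_rescues_low_iou(self):
        truth = np.zeros((40, 40), bool)
        truth[10:30, 10:30] = True
        pred = np.zeros_like(truth)
        pred[18:22, 18:22] = True  # tiny but centered inside the truth
        assert cs.extraction_accepted(pred, truth)

    def test_translation_invariance_of_metrics(self, rng):
        pred = np.zeros((30, 30), bool)
        truth = np.zeros((30, 30), bool)
        pred[5:12, 5:14] = True
        truth[6:13, 4:12] = True
        m1 = cs.compute_metrics(cs.count_pixels(pred, truth))
        m2 = cs.compute_metrics(
            cs.count_pixels(np.roll(pred, (9, 9), (0, 1)), np.roll(truth, (9, 9), (0, 1)))
        )
        assert m1 == m2


class TestBenchmark:
    @pytest.fixture
    def planted(self):
        """Four frames with hand-planted predictions of known quality."""
        truths = []
        for side in (8, 10, 12, 14):
            t = np.zeros((40, 40), bool)
            t[10 : 10 + side, 10 : 10 + side] = True
            truths.append(t)
        pairs = [(np.zeros((40, 40), np.uint8), t) for t in truths]
        return pairs, truths

    def test_perfect_and_empty_methods(self, planted):
        pairs, truths = planted
        it = iter(truths * 10)
        methods = {
            "perfect": lambda img: next(it),
            "empty": lambda img: np.zeros((40, 40), bool),
        }
        df, summary = cs.benchmark(pairs, methods=methods)
        perf = summary["methods"]["perfect"]
        assert perf["ext_rate_pct"] == 100.0
        assert all(perf[f"mean_{m}_pct"] == 100.0 for m in ("accuracy", "recall", "precision", "f1"))
        empty = summary["methods"]["empty"]
        assert empty["ext_rate_pct"] == 0.0
        assert empty["mean_precision_pct"] is None

    def test_hand_worked_mixed_method(self, planted):
        pairs, truths = planted
        # predict the truth eroded by dropping its last row: known counts
        preds = [t.copy() for t in truths]
        for t, side in zip(preds, (8, 10, 12, 14)):
            t[10 + side - 1, :] = False
        it = iter(preds)
        df, summary = cs.benchmark(pairs, methods={"eroded": lambda img: next(it)})
        sub = df[df["method"] == "eroded"]
        for (_, row), side in zip(sub.iterrows(), (8, 10, 12, 14)):
            assert row["tp"] == side * (side - 1)
            assert row["fp"] == 0 and row["fn"] == side
            assert row["precision"] == 100.0
            assert row["recall"] == pytest.approx(100.0 * (side - 1) / side)
        entry = summary["methods"]["eroded"]
        assert entry["extractions"] == 4
        expected_recall = np.mean([100.0 * (s - 1) / s for s in (8, 10, 12, 14)])
        assert entry["mean_recall_pct"] == pytest.approx(expected_recall)

    def test_size_split_groups_by_median_area(self, planted):
        pairs, truths = planted
        it = iter(truths * 10)
        df, summary = cs.benchmark(pairs, methods={"perfect": lambda img: next(it)})
        groups = df.groupby("group")["truth_area"].max()
        assert groups["small"] < groups["large"]
        by_group = summary["methods"]["perfect"]["by_group"]
        assert by_group["large"]["n"] + by_group["small"]["n"] == 4

    def test_wilcoxon_reported_for_fcm_vs_proposed(self, planted):
        pairs, truths = planted
        it1, it2 = iter(truths * 10), iter(truths * 10)
        df, summary = cs.benchmark(
            pairs,
            methods={"fcm": lambda img: next(it1), "proposed": lambda img: next(it2)},
        )
        # identical predictions -> no signed-rank test possible, reported None
        assert summary["wilcoxon_accuracy_proposed_vs_fcm_p"] is None
        assert summary["jointly_accepted"] == 4

    def test_needs_at_least_two_images(self, planted):
        pairs, _ = planted
        with pytest.raises(ValueError):
            cs.benchmark(pairs[:1], methods={"m": lambda img: img > 0})
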