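import itertools

import numpy as np
import pytest

from pcmfiber import (
    iou,
    match_detections,
    precision,
    recall,
    report_from_counts,
    tabulate,
)
from pcmfiber.datasets import evaluation_counts, model_count_rows
from pcmfiber.evaluation import ImageMatch, percent


def pixset(*rowcols):
    return np.array(rowcols, dtype=int)


def block(r0, c0, h, w):
    return np.argwhere(np.ones((h, w), bool)) + [r0, c0]


class TestIoU:
    def test_identical_sets(self):
        a = block(0, 0, 5, 5)
        assert iou(a, a, mode="union") == 1.0
        assert iou(a, a, mode="sum") == 0.5

    def test_disjoint_sets(self):
        assert iou(block(0, 0, 3, 3), block(10, 10, 3, 3), mode="union") == 0.0
        assert iou(block(0, 0, 3, 3), block(10, 10, 3, 3), mode="sum") == 0.0

    def test_half_overlap_arithmetic(self):
        a = block(0, 0, 10, 10)   # 100 px
        b = block(5, 0, 10, 10)   # 100 px, overlap 50
        assert iou(a, b, mode="union") == pytest.approx(50 / 150)
        assert iou(a, b, mode="sum") == pytest.approx(50 / 200)

    def test_symmetric_and_bounded(self, rng):
        for _ in range(20):
            a = block(*rng.integers(0, 8, 2), *rng.integers(1, 8, 2))
            b = block(*rng.integers(0, 8, 2), *rng.integers(1, 8, 2))
            v = iou(a, b)
            assert v == iou(b, a)
            assert 0.0 <= v <= 1.0
            assert (v == 1.0) == (set(map(tuple, a)) == set(map(tuple, b)))

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError):
            iou(np.empty((0, 2)), block(0, 0, 2, 2))

    def test_bad_mode_rejected(self):
        with pytest.raises(ValueError):
            iou(block(0, 0, 2, 2), block(0, 0, 2, 2), mode="dice")


def brute_force_best_assignment(preds, truths, threshold=0.5):
    """Exhaustive one-to-one assignment maximizing (matches, total IoU)."""
    qual = {}
    for i, p in enumerate(preds):
        for j, t in enumerate(truths):
            v = iou(p, t)
            if v >= threshold:
                qual[(i, j)] = v
    best = (0, 0.0)
    idx_p = range(len(preds))
    for k in range(min(len(preds), len(truths)), -1, -1):
        for ps in itertools.permutations(idx_p, k):
            for ts in itertools.combinations(range(len(truths)), k):
                for perm_t in itertools.permutations(ts):
                    pairs = list(zip(ps, perm_t))
                    if all(pr in qual for pr in pairs):
                        total = sum(qual[pr] for pr in pairs)
                        best = max(best, (k, total))
    return best


def random_instance(rng, max_n=5):
    """Disjoint truths on a grid plus perturbed/spurious predictions."""
    n_t = int(rng.integers(0, max_n + 1))
    truths = []
    for j in range(n_t):
        r0, c0 = 10 * j, int(rng.integers(0, 5))
        truths.append(block(r0, c0, int(rng.integers(2, 6)), int(rng.integers(2, 6))))
    preds = []
    for j in range(n_t):
        if rng.random() < 0.8:  # jittered copy of a truth
            preds.append(truths[j] + rng.integers(-1, 2, size=2))
    for _ in range(int(rng.integers(0, 3))):  # spurious
        preds.append(block(int(rng.integers(50, 80)), int(rng.integers(0, 9)),
                           int(rng.integers(1, 5)), int(rng.integers(1, 5))))
    return preds, truths


class TestMatching:
    def test_identical_prediction_and_truth(self):
        sets = [block(0, 0, 4, 4), block(20, 0, 3, 6)]
        m = match_detections(sets, sets)
        assert (m.tp, m.overlooked, m.overcounted) == (2, 0, 0)

    def test_nine_clean_matches_like_max_density_field(self):
        # nine expert fibers, nine predictions each overlapping its truth
        truths = [block(12 * j, 0, 3, 8) for j in range(9)]
        preds = [t + [0, 1] for t in truths]
        m = match_detections(preds, truths, image_id="Amo-5-A4")
        assert (m.counted, m.overlooked, m.overcounted) == (9, 0, 0)

    def test_one_to_one_no_double_matching(self):
        truth = [block(0, 0, 4, 4), block(0, 6, 4, 4)]
        # one prediction spanning both truths plus one good copy
        preds = [np.vstack([truth[0], truth[1]]), truth[0]]
        m = match_detections(preds, truth)
        used_p = [i for i, _, _ in m.matches]
        used_t = [j for _, j, _ in m.matches]
        assert len(used_p) == len(set(used_p))
        assert len(used_t) == len(set(used_t))

    @pytest.mark.parametrize("trial", range(30))
    def test_greedy_equals_exhaustive_on_small_instances(self, rng, trial):
        preds, truths = random_instance(rng)
        if not preds or not truths:
            m = match_detections(preds, truths)
            assert m.tp == 0
            return
        m = match_detections(preds, truths, strategy="greedy")
        best_k, _ = brute_force_best_assignment(preds, truths)
        assert m.tp == best_k
        m_opt = match_detections(preds, truths, strategy="optimal")
        assert m_opt.tp == best_k

    @pytest.mark.parametrize("trial", range(15))
    def test_count_conservation(self, rng, trial):
        preds, truths = random_instance(rng)
        m = match_detections(preds, truths)
        assert m.tp + m.overlooked == len(truths)
        assert m.tp + m.overcounted == len(preds)
        assert all(v >= 0.5 for _, _, v in m.matches)

    def test_threshold_validated(self):
        with pytest.raises(ValueError):
            match_detections([], [], iou_threshold=0.0)


class TestRecallPrecision:
    def test_semantic_model_reference_counts(self):
        assert recall(52, 3) == pytest.approx(52 / 55)
        assert percent(recall(52, 3)) == 95
        assert precision(52, 5) == pytest.approx(52 / 57)
        assert percent(precision(52, 5)) == 91

    def test_instance_model_reference_counts(self):
        # Eqs. applied to the instance model's totals (34 TP, 21 FN, 7 FP)
        assert round(100 * recall(34, 21), 1) == 61.8
        assert round(100 * precision(34, 7), 1) == 82.9

    def test_perfect_and_undefined(self):
        assert recall(5, 0) == 1.0
        assert precision(5, 0) == 1.0
        assert recall(0, 0) is None
        assert precision(0, 0) is None

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            recall(-1, 2)


class TestTabulate:
    def test_reference_table_totals(self):
        report = report_from_counts(model_count_rows("ma_net"))
        assert report.totals == ("Total", 55, 57, 3, 5)
        assert (report.tp, report.fn, report.fp) == (52, 3, 5)
        assert report.recall_percent == 95
        assert report.precision_percent == 91

    def test_single_image_report_is_its_own_total(self):
        m = ImageMatch("img", expert_count=4, counted=5, overlooked=1, overcounted=2, tp=3)
        rep = tabulate([m])
        assert rep.totals[1:] == (4, 5, 1, 2)

    def test_totals_are_column_sums(self, rng):
        ms = []
        for i in range(10):
            tp = int(rng.integers(0, 8))
            fn = int(rng.integers(0, 5))
            fp = int(rng.integers(0, 5))
            ms.append(ImageMatch(f"i{i}", tp + fn, tp + fp, fn, fp, tp))
        rep = tabulate(ms)
        for col in range(1, 5):
            assert rep.totals[col] == sum(r[col] for r in rep.per_image)
        assert rep.tp + rep.fn == rep.totals[1]
        assert rep.tp + rep.fp == rep.totals[2]

    def test_frame_has_totals_row(self):
        frame = report_from_counts(model_count_rows("mask_rcnn")).to_frame()
        assert len(frame) == 11
        assert frame.iloc[-1]["image"] == "Total"
        assert frame.iloc[-1]["counted"] == 41

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            tabulate([])


def test_reference_counts_rows_are_internally_consistent():
    df = evaluation_counts()
    assert df["expert"].sum() == 55
    for model in ("mask_rcnn", "ma_net"):
        derived = df[f"{model}_counted"] - df[f"{model}_overcounted"] + df[f"{model}_overlooked"]
        assert (derived == df["expert"]).all()
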