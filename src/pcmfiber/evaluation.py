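"""Detection evaluation: IoU matching against expert annotations and the
counted / overlooked / overcounted bookkeeping with pooled recall/precision.

Terminology follows fiber-counting practice: a prediction matched one-to-one
to an expert fiber at IoU >= threshold is a true positive ("counted"
includes these plus any overcounts); an unmatched expert fiber is
"overlooked" (false negative); an unmatched prediction is "overcounted"
(false positive).  Recall = TP/(TP+FN), precision = TP/(TP+FP).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .counting import round_half_up


def _as_tuple_set(pixels) -> set[tuple[int, int]]:
    arr = np.asarray(pixels)
    if arr.size == 0:
        raise ValueError("pixel set must be non-empty")
    return set(map(tuple, arr.reshape(-1, 2).tolist()))


def iou(pixels_a, pixels_b, mode: str = "union") -> float:
    """Overlap ratio between two pixel sets.

    mode="union": |A n B| / |A u B| (the standard intersection-over-union);
    mode="sum":   |A n B| / (|A| + |B|) (overlap divided by the sum of the
    two areas).  Both are exposed because counting protocols in the wild
    state one while naming the other; union is the default.
    """
    if mode not in ("union", "sum"):
        raise ValueError(f"mode must be 'union' or 'sum', got {mode!r}")
    a, b = _as_tuple_set(pixels_a), _as_tuple_set(pixels_b)
    inter = len(a & b)
    denom = len(a | b) if mode == "union" else len(a) + len(b)
    return inter / denom


@dataclass
class ImageMatch:
    """Match bookkeeping for one image."""

    image_id: str
    expert_count: int
    counted: int
    overlooked: int
    overcounted: int
    tp: int
    matches: list[tuple[int, int, float]] = field(default_factory=list)


@dataclass
class MatchReport:
    """Pooled evaluation over a set of images.

    Invariants: counted = tp + fp and expert_count = tp + fn, per image and
    in totals; matches are one-to-one with IoU >= the configured threshold.
    Recall/precision are ``None`` when their denominator is zero.
    """

    per_image: list[tuple[str, int, int, int, int]]
    tp: int
    fn: int
    fp: int
    matches: list[tuple[str, int, int, float]] = field(default_factory=list)

    @property
    def totals(self) -> tuple[str, int, int, int, int]:
        return (
            "Total",
            sum(r[1] for r in self.per_image),
            sum(r[2] for r in self.per_image),
            sum(r[3] for r in self.per_image),
            sum(r[4] for r in self.per_image),
        )

    @property
    def recall(self) -> float | None:
        return recall(self.tp, self.fn)

    @property
    def precision(self) -> float | None:
        return precision(self.tp, self.fp)

    @property
    def recall_percent(self) -> int | None:
        return None if self.recall is None else percent(self.recall)

    @property
    def precision_percent(self) -> int | None:
        return None if self.precision is None else percent(self.precision)

    def to_frame(self) -> pd.DataFrame:
        rows = list(self.per_image) + [self.totals]
        return pd.DataFrame(
            rows, columns=["image", "expert_count", "counted", "overlooked", "overcounted"]
        )

    def to_dict(self) -> dict:
        return {
            "tp": self.tp,
            "fn": self.fn,
            "fp": self.fp,
            "recall": self.recall,
            "precision": self.precision,
            "recall_percent": self.recall_percent,
            "precision_percent": self.precision_percent,
            "per_image": [list(r) for r in self.per_image],
            "totals": list(self.totals),
        }


def recall(tp: int, fn: int) -> float | None:
    """TP / (TP + FN); None (undefined) when there are no expert fibers."""
    if tp < 0 or fn < 0:
        raise ValueError("counts must be non-negative")
    if tp + fn == 0:
        return None
    return tp / (tp + fn)


def precision(tp: int, fp: int) -> float | None:
    """TP / (TP + FP); None (undefined) when there are no predictions."""
    if tp < 0 or fp < 0:
        raise ValueError("counts must be non-negative")
    if tp + fp == 0:
        return None
    return tp / (tp + fp)


def percent(fraction: float) -> int:
    """Fraction -> integer percent, rounded half-up (report formatting)."""
    return int(round_half_up(fraction * 100.0, 0))


def match_detections(
    predictions,
    truth,
    iou_threshold: float = 0.5,
    mode: str = "union",
    strategy: str = "greedy",
    image_id: str = "",
) -> ImageMatch:
    """One-to-one matching of predicted to ground-truth pixel sets.

    strategy="greedy": qualified pairs (IoU >= threshold) are taken in
    descending IoU order, ties broken by smaller prediction index then
    smaller truth index.  strategy="optimal": exhaustive one-to-one
    assignment maximizing the number of qualified matches, then total IoU
    (audit mode; exponential in the smaller side, intended for small fields).
    """
    if not 0 < iou_threshold <= 1:
        raise ValueError(f"iou_threshold must be in (0, 1], got {iou_threshold}")
    preds = list(predictions)
    truths = list(truth)
    n_p, n_t = len(preds), len(truths)

    pairs = []
    for i, p in enumerate(preds):
        for j, t in enumerate(truths):
            v = iou(p, t, mode=mode)
            if v >= iou_threshold:
                pairs.append((i, j, v))

    if strategy == "greedy":
        matches = _greedy(pairs)
    elif strategy == "optimal":
        matches = _optimal(pairs, n_p, n_t)
    else:
        raise ValueError(f"unknown strategy {strategy!r}")

    tp = len(matches)
    return ImageMatch(
        image_id=image_id,
        expert_count=n_t,
        counted=n_p,
        overlooked=n_t - tp,
        overcounted=n_p - tp,
        tp=tp,
        matches=matches,
    )


def _greedy(pairs):
    matches = []
    used_p, used_t = set(), set()
    for i, j, v in sorted(pairs, key=lambda x: (-x[2], x[0], x[1])):
        if i not in used_p and j not in used_t:
            matches.append((i, j, v))
            used_p.add(i)
            used_t.add(j)
    return matches


def _optimal(pairs, n_p, n_t):
    by_pred: dict[int, list] = {}
    for i, j, v in pairs:
        by_pred.setdefault(i, []).append((j, v))
    pred_ids = sorted(by_pred)

    best = ([], -1.0)
    def recurse(k, used_t, current, total):
        nonlocal best
        if (len(current), total) > (len(best[0]), best[1]):
            best = (list(current), total)
        if k == len(pred_ids):
            return
        # upper-bound prune: even matching every remaining pred can't win
        if len(current) + (len(pred_ids) - k) < len(best[0]):
            return
        i = pred_ids[k]
        for j, v in by_pred[i]:
            if j not in used_t:
                current.append((i, j, v))
                used_t.add(j)
                recurse(k + 1, used_t, current, total + v)
                used_t.discard(j)
                current.pop()
        recurse(k + 1, used_t, current, total)

    recurse(0, set(), [], 0.0)
    return sorted(best[0])


def tabulate(per_image_reports) -> MatchReport:
    """Pool per-image matches into totals with micro-averaged recall/precision."""
    reports = list(per_image_reports)
    if not reports:
        raise ValueError("need at least one per-image report")
    per_image = [
        (r.image_id, r.expert_count, r.counted, r.overlooked, r.overcounted) for r in reports
    ]
    tp = sum(r.tp for r in reports)
    fn = sum(r.overlooked for r in reports)
    fp = sum(r.overcounted for r in reports)
    matches = [(r.image_id, i, j, v) for r in reports for (i, j, v) in r.matches]
    return MatchReport(per_image=per_image, tp=tp, fn=fn, fp=fp, matches=matches)


def report_from_counts(rows) -> MatchReport:
    """Build a MatchReport from published bookkeeping rows.

    Each row is (image_id, counted, overlooked, overcounted); true positives
    are recovered as counted - overcounted and the expert count as
    tp + overlooked.
    """
    reports = []
    for image_id, counted, overlooked, overcounted in rows:
        tp = counted - overcounted
        if tp < 0:
            raise ValueError(f"{image_id}: overcounted exceeds counted")
        reports.append(
            ImageMatch(
                image_id=image_id,
                expert_count=tp + overlooked,
                counted=counted,
                overlooked=overlooked,
                overcounted=overcounted,
                tp=tp,
            )
        )
    return tabulate(reports)
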