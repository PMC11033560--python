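"""Published reference counts for fiber-detection evaluation.

Ten phase-contrast fields from simulated atmospheric samples — five amosite
("Amo") and five chrysotile ("Chr") slides, fields named slide-row-column —
with the expert analyst's reference count and the counted / overlooked /
overcounted bookkeeping of two segmentation models evaluated against that
expert: an instance-segmentation model (Mask R-CNN style) and a semantic-
segmentation model (MA-Net style).  Every row satisfies
``expert = counted - overcounted + overlooked``.
"""

from __future__ import annotations

import pandas as pd

MODELS = ("mask_rcnn", "ma_net")

# image, expert, (counted, overlooked, overcounted) per model
_ROWS = [
    ("Amo-1-B1", 2, (4, 0, 2), (3, 0, 1)),
    ("Amo-2-C4", 5, (5, 1, 1), (6, 0, 1)),
    ("Amo-3-B5", 4, (5, 0, 1), (4, 0, 0)),
    ("Amo-4-H3", 5, (4, 3, 2), (6, 0, 1)),
    ("Amo-5-A4", 9, (6, 3, 0), (9, 0, 0)),
    ("Chr-1-D2", 5, (1, 4, 0), (5, 0, 0)),
    ("Chr-3-B5", 5, (3, 2, 0), (6, 0, 1)),
    ("Chr-4-A2", 9, (7, 2, 0), (8, 1, 0)),
    ("Chr-5-E3", 3, (2, 2, 1), (4, 0, 1)),
    ("Chr-5-E4", 8, (4, 4, 0), (6, 2, 0)),
]


def evaluation_counts() -> pd.DataFrame:
    """The reference evaluation table as a tidy DataFrame.

    Columns: image, expert, then ``<model>_counted`` / ``<model>_overlooked``
    / ``<model>_overcounted`` for each of ``mask_rcnn`` and ``ma_net``.
    """
    records = []
    for image, expert, rcnn, manet in _ROWS:
        rec = {"image": image, "expert": expert}
        for model, (c, o, oc) in zip(MODELS, (rcnn, manet)):
            rec[f"{model}_counted"] = c
            rec[f"{model}_overlooked"] = o
            rec[f"{model}_overcounted"] = oc
        records.append(rec)
    return pd.DataFrame.from_records(records)


def model_count_rows(model: str) -> list[tuple[str, int, int, int]]:
    """Bookkeeping rows (image, counted, overlooked, overcounted) for one
    model, as consumed by :func:`pcmfiber.evaluation.report_from_counts`."""
    if model not in MODELS:
        raise ValueError(f"model must be one of {MODELS}, got {model!r}")
    idx = MODELS.index(model)
    return [(image, *((rcnn, manet)[idx])) for image, _, rcnn, manet in _ROWS]
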