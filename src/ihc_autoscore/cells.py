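"""Cell detection data model, matching, suppression and mAP evaluation.

The four-class label set for detected cells is the cross of tumor vs
non-tumor and PTEN-positive (DAB staining present) vs PTEN-negative
(staining absent). Matching between detections and reference annotations —
both for annotation refinement and for average-precision evaluation — uses
mask intersection-over-union with a boundary-inclusive threshold
(IoU >= threshold counts as a match), 0.5 by default.

The mAP dialect is: per class, rank detections by confidence, greedily match
each to the highest-IoU unmatched ground-truth instance of that class at
IoU >= 0.5, build the precision-recall curve, and integrate it with
all-point interpolation (area under the precision envelope). mAP is the
unweighted mean of the per-class APs over classes present in the truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Sequence

import numpy as np

from .masks import mask_iou

IOU_MATCH_THRESHOLD = 0.5

__all__ = [
    "CellClass", "CellDetection", "CellAnnotation", "AnnotationRevision",
    "non_max_suppression", "match_detections", "average_precision",
    "mean_average_precision", "refine_annotations", "IOU_MATCH_THRESHOLD",
]


class CellClass(str, Enum):
    TUMOR_POS = "tumor+"
    TUMOR_NEG = "tumor-"
    NONTUMOR_POS = "nontumor+"
    NONTUMOR_NEG = "nontumor-"

    @property
    def is_tumor(self) -> bool:
        return self in (CellClass.TUMOR_POS, CellClass.TUMOR_NEG)

    @property
    def is_positive(self) -> bool:
        return self in (CellClass.TUMOR_POS, CellClass.NONTUMOR_POS)


@dataclass
class CellDetection:
    """One detected cell instance within a tile."""

    mask: np.ndarray                 # boolean, tile-local
    cell_class: CellClass
    confidence: float = 1.0

    def __post_init__(self):
        self.mask = np.asarray(self.mask, dtype=bool)
        if not self.mask.any():
            raise ValueError("detection mask must be non-empty")
        if not 0.0 <= self.confidence <= 1.0:
            raise ValueError(f"confidence {self.confidence} outside [0, 1]")
        self.cell_class = CellClass(self.cell_class)

    @property
    def centroid(self) -> tuple[float, float]:
        ys, xs = np.nonzero(self.mask)
        return (float(xs.mean()), float(ys.mean()))


@dataclass
class CellAnnotation:
    """A reference (ground-truth or reviewer) cell instance."""

    mask: np.ndarray
    cell_class: CellClass

    def __post_init__(self):
        self.mask = np.asarray(self.mask, dtype=bool)
        if not self.mask.any():
            raise ValueError("annotation mask must be non-empty")
        self.cell_class = CellClass(self.cell_class)


@dataclass
class AnnotationRevision:
    """Outcome of one round of annotation refinement."""

    original: list[CellAnnotation]
    added: list[CellAnnotation]          # unmatched detections, reviewer-labeled
    merged: list[CellAnnotation] = field(init=False)

    def __post_init__(self):
        self.merged = list(self.original) + list(self.added)


def non_max_suppression(detections: Sequence[CellDetection],
                        iou_threshold: float = IOU_MATCH_THRESHOLD
                        ) -> list[CellDetection]:
    """Confidence-ranked suppression of overlapping proposals.

    Proposals are visited in decreasing confidence (ties broken by input
    order); a proposal is dropped when its mask IoU with any kept proposal
    reaches the threshold.
    """
    order = sorted(range(len(detections)),
                   key=lambda k: (-detections[k].confidence, k))
    kept: list[CellDetection] = []
    for k in order:
        d = detections[k]
        if all(mask_iou(d.mask, kk.mask) < iou_threshold for kk in kept):
            kept.append(d)
    return kept


def match_detections(detections: Sequence[CellDetection],
                     references: Sequence[CellAnnotation],
                     iou_threshold: float = IOU_MATCH_THRESHOLD,
                     class_aware: bool = True) -> list[int | None]:
    """Greedy one-to-one matching of detections to reference instances.

    Detections are visited in decreasing confidence; each takes the
    unmatched reference with the highest IoU, provided IoU >= threshold
    (boundary inclusive) and, when ``class_aware``, the classes agree.
    Returns, per detection (input order), the matched reference index or
    None.
    """
    order = sorted(range(len(detections)),
                   key=lambda k: (-detections[k].confidence, k))
    assigned: list[int | None] = [None] * len(detections)
    taken = np.zeros(len(references), dtype=bool)
    for k in order:
        d = detections[k]
        best, best_iou = None, -1.0
        for r_idx, ref in enumerate(references):
            if taken[r_idx]:
                continue
            if class_aware and ref.cell_class != d.cell_class:
                continue
            iou = mask_iou(d.mask, ref.mask)
            if iou >= iou_threshold and iou > best_iou:
                best, best_iou = r_idx, iou
        if best is not None:
            assigned[k] = best
            taken[best] = True
    return assigned


def average_precision(detections: Sequence[CellDetection],
                      truth: Sequence[CellAnnotation],
                      iou_threshold: float = IOU_MATCH_THRESHOLD) -> float:
    """All-point-interpolated AP for a single class at the given IoU."""
    n_truth = len(truth)
    if n_truth == 0:
        raise ValueError("average precision needs non-empty truth")
    if len(detections) == 0:
        return 0.0
    assigned = match_detections(detections, truth, iou_threshold,
                                class_aware=False)
    order = sorted(range(len(detections)),
                   key=lambda k: (-detections[k].confidence, k))
    tp = np.array([assigned[k] is not None for k in order], dtype=float)
    cum_tp = np.cumsum(tp)
    precision = cum_tp / np.arange(1, len(order) + 1)
    recall = cum_tp / n_truth
    # precision envelope, integrated over every recall step
    env = np.maximum.accumulate(precision[::-1])[::-1]
    ap = 0.0
    prev_r = 0.0
    for p, r in zip(env, recall):
        ap += p * (r - prev_r)
        prev_r = r
    return float(ap)


def mean_average_precision(detections: Sequence[CellDetection],
                           truth: Sequence[CellAnnotation],
                           iou_threshold: float = IOU_MATCH_THRESHOLD) -> float:
    """Unweighted mean of per-class APs over classes present in the truth."""
    if len(truth) == 0:
        raise ValueError("mAP needs non-empty truth")
    classes = sorted({t.cell_class for t in truth}, key=lambda c: c.value)
    aps = []
    for cls in classes:
        cls_truth = [t for t in truth if t.cell_class == cls]
        cls_det = [d for d in detections if d.cell_class == cls]
        aps.append(average_precision(cls_det, cls_truth, iou_threshold))
    return float(np.mean(aps))


def refine_annotations(detections: Sequence[CellDetection],
                       annotations: Sequence[CellAnnotation],
                       reviewer_labels: dict[int, CellClass] | None = None,
                       iou_threshold: float = IOU_MATCH_THRESHOLD
                       ) -> AnnotationRevision:
    """Merge reviewer-labeled unmatched detections into the annotation set.

    A detection is unmatched when its IoU with every original annotation is
    below the threshold (class labels are ignored for matching, mirroring a
    reviewer deciding whether a detection hits *some* annotated cell).
    ``reviewer_labels`` maps detection index -> four-class label; a label
    must be supplied for every unmatched detection.
    """
    reviewer_labels = reviewer_labels or {}
    assigned = match_detections(detections, annotations, iou_threshold,
                                class_aware=False)
    added = []
    for idx, (det, ref) in enumerate(zip(detections, assigned)):
        if ref is not None:
            continue
        if idx not in reviewer_labels:
            raise ValueError(
                f"unmatched detection {idx} has no reviewer label")
        added.append(CellAnnotation(mask=det.mask,
                                    cell_class=CellClass(reviewer_labels[idx])))
    return AnnotationRevision(original=list(annotations), added=added)
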