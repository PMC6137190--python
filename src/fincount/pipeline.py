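"""End-to-end glue: segment a sequence, auto-label RoIs against ground
truth, train the classifier, and produce recognized count series.

Auto-labelling replaces the manual labelling of candidate regions when the
sequence comes with exact ground truth (synthetic data): a RoI is positive
iff the filled convex hull overlaps some true fish mask with
intersection-over-union at or above a permissive threshold — partial-fish
regions are legitimate positives, so the threshold is deliberately low.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from skimage.draw import polygon as draw_polygon

from .features import FEATURE_NAMES, feature_matrix
from .gp import CVReport, GPClassifierEnsemble, GPConfig, balanced_cv
from .io import AnnotationRecord, FrameSequence, sample_training_frames
from .segmentation import RoI, SegmentationParams, segment_frame
from .synthetic import GroundTruth

IOU_POSITIVE_THRESHOLD = 0.3


def hull_mask(roi: RoI, frame_shape: tuple[int, int]) -> np.ndarray:
    """Rasterised filled convex hull of a RoI on the full frame grid."""
    m = np.zeros(frame_shape, dtype=bool)
    rr, cc = draw_polygon(roi.hull[:, 0], roi.hull[:, 1], shape=frame_shape)
    m[rr, cc] = True
    return m


def iou(a: np.ndarray, b: np.ndarray) -> float:
    inter = np.logical_and(a, b).sum()
    union = np.logical_or(a, b).sum()
    return float(inter / union) if union else 0.0


def auto_label_rois(
    rois: Sequence[RoI],
    fish_masks: Sequence[np.ndarray],
    frame_shape: tuple[int, int],
    iou_threshold: float = IOU_POSITIVE_THRESHOLD,
) -> np.ndarray:
    """Label each RoI 1 iff its hull IoU with any true fish mask >= threshold."""
    labels = np.zeros(len(rois), dtype=np.int64)
    for i, roi in enumerate(rois):
        hm = hull_mask(roi, frame_shape)
        for fm in fish_masks:
            if iou(hm, fm) >= iou_threshold:
                labels[i] = 1
                break
    return labels


@dataclass
class LabeledPool:
    """Feature matrix + binary labels + originating frame ids."""

    X: np.ndarray
    y: np.ndarray
    frame_ids: list[str]

    @property
    def n_positive(self) -> int:
        return int(self.y.sum())

    @property
    def n_negative(self) -> int:
        return int((self.y == 0).sum())


def build_labeled_pool(
    seq: FrameSequence,
    annotations: Sequence[AnnotationRecord],
    truth: GroundTruth,
    seg_params: Optional[SegmentationParams] = None,
    fraction: float = 1.0,
    rng_seed: int = 0,
    iou_threshold: float = IOU_POSITIVE_THRESHOLD,
) -> LabeledPool:
    """Segment (a photoperiod-stratified sample of) the sequence and
    auto-label every extracted RoI against the ground truth."""
    seg_params = seg_params or SegmentationParams()
    if fraction < 1.0:
        chosen = set(sample_training_frames(seq, annotations, fraction, rng_seed))
    else:
        chosen = {f.frame_id for f in seq.frames}
    rows, labels, fids = [], [], []
    for i in range(1, len(seq)):
        if seq[i].frame_id not in chosen:
            continue
        if truth.error_frames[i] or truth.error_frames[i - 1]:
            continue
        if not (truth.ptz_ok[i] and truth.ptz_ok[i - 1]):
            continue
        rois = segment_frame(seq, i, seg_params)
        if not rois:
            continue
        X = feature_matrix(rois)
        y = auto_label_rois(rois, truth.fish_masks(i), truth.frame_shape, iou_threshold)
        rows.append(X)
        labels.append(y)
        fids.extend([seq[i].frame_id] * len(rois))
    if not rows:
        return LabeledPool(
            X=np.empty((0, len(FEATURE_NAMES))), y=np.empty(0, dtype=np.int64), frame_ids=[]
        )
    return LabeledPool(X=np.vstack(rows), y=np.concatenate(labels), frame_ids=fids)


def build_pooled_examples(
    datasets: Sequence[tuple[FrameSequence, Sequence[AnnotationRecord], GroundTruth]],
    seg_params: Optional[SegmentationParams] = None,
    fraction: float = 1.0,
    rng_seed: int = 0,
    iou_threshold: float = IOU_POSITIVE_THRESHOLD,
) -> LabeledPool:
    """Concatenate labeled pools from several sequences.

    Training data should span the acquisition conditions the classifier
    will face (clear and turbid water, fouling levels, day and night), the
    way a year-round sample of a real deployment does; this helper builds
    one pool from a list of per-condition sequences.
    """
    pools = [
        build_labeled_pool(s, a, t, seg_params, fraction=fraction, rng_seed=rng_seed,
                           iou_threshold=iou_threshold)
        for s, a, t in datasets
    ]
    return LabeledPool(
        X=np.vstack([p.X for p in pools]),
        y=np.concatenate([p.y for p in pools]),
        frame_ids=[f for p in pools for f in p.frame_ids],
    )


def train_on_sequence(
    seq: FrameSequence,
    annotations: Sequence[AnnotationRecord],
    truth: GroundTruth,
    seg_params: Optional[SegmentationParams] = None,
    gp_config: Optional[GPConfig] = None,
    k: int = 10,
    repeats: int = 10,
    fraction: float = 1.0,
    rng_seed: int = 0,
) -> tuple[GPClassifierEnsemble, CVReport]:
    """Full training workflow: sample -> segment -> auto-label -> balanced CV."""
    pool = build_labeled_pool(
        seq, annotations, truth, seg_params, fraction=fraction, rng_seed=rng_seed
    )
    if pool.n_positive == 0:
        raise ValueError(
            "no positive examples found: segmentation produced no RoIs overlapping "
            "true fish (check segmentation parameters and scene contrast)"
        )
    return balanced_cv(
        pool.X,
        pool.y,
        k=k,
        repeats=repeats,
        rng_seed=rng_seed,
        config=gp_config,
        feature_names=FEATURE_NAMES,
    )
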