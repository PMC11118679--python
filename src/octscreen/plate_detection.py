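"""Tissue detection in plate-view well images, and detector evaluation.

The screening instrument photographs each well with a webcam and must decide
whether the well holds an explant and, if so, where — the detected centroid
is converted to stage voltages that steer the OCT beam onto the tissue.
This module provides a deterministic classical detector (robust background
threshold + connected components), the standard single-class evaluation
metrics (IoU, mAP over an IoU-threshold grid, centroid shift), and the
centroid-to-stage affine conversion.

Box convention: half-open, 0-based, x = column, y = row; mm coordinates have
their origin at the image's top-left corner with pixel centers at
``(index + 0.5) * mm_per_pixel``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import ndimage
from skimage import measure

from .errors import ParameterError, UndefinedStatisticError

IOU_THRESHOLDS = np.round(np.arange(0.50, 0.951, 0.05), 2)


@dataclass(frozen=True)
class BoundingBox:
    """Axis-aligned half-open pixel box with an optional confidence score."""

    x0: float
    y0: float
    x1: float
    y1: float
    confidence: float = 1.0

    def __post_init__(self) -> None:
        if not (self.x0 < self.x1 and self.y0 < self.y1):
            raise ParameterError("degenerate bounding box")
        if self.x0 < 0 or self.y0 < 0:
            raise ParameterError("box coordinates must be non-negative")

    @property
    def area(self) -> float:
        return (self.x1 - self.x0) * (self.y1 - self.y0)


@dataclass
class DetectionResult:
    """Outcome of tissue detection: a located box/centroid, or explicit void."""

    status: str  # "found" | "void"
    box: Optional[BoundingBox] = None
    centroid_mm: Optional[tuple[float, float]] = None

    def __post_init__(self) -> None:
        if self.status not in ("found", "void"):
            raise ParameterError(f"invalid status {self.status!r}")
        if (self.status == "void") != (self.box is None
                                       and self.centroid_mm is None):
            raise ParameterError("void results carry no box/centroid and "
                                 "found results carry both")


@dataclass
class StageCalibration:
    """Webcam-to-OCT offset and mm/volt scales of the motorized stages."""

    webcam_to_oct_offset_mm: tuple[float, float] = (0.0, 0.0)
    mm_per_volt: tuple[float, float] = (1.0, 1.0)
    reference_voltage: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        if 0.0 in self.mm_per_volt:
            raise ParameterError("mm_per_volt components must be nonzero")


# ---------------------------------------------------------------------------
# Classical baseline detector
# ---------------------------------------------------------------------------

def detect_tissue_baseline(
    image: np.ndarray,
    mm_per_pixel: float,
    *,
    background_quantile: float = 0.5,
    min_area_mm2: float = 1.0,
    smoothing_scale_mm: float = 0.25,
    threshold_sigmas: float = 6.0,
) -> DetectionResult:
    """Locate the explant in a well image or report an explicit void.

    The image is Gaussian-smoothed, the background level is estimated as a
    robust quantile, and pixels deviating from it by more than
    ``threshold_sigmas`` robust noise SDs (MAD-based) are kept. Connected
    components smaller than ``min_area_mm2`` are discarded; if none remain
    the well is void. Otherwise the largest component (ties: smaller
    top-left corner in row-major order) yields the tight half-open bounding
    box and its intensity-weighted centroid in mm.
    """
    image = np.asarray(image, dtype=np.float64)
    if image.ndim == 3:  # RGB -> luminance
        image = image.mean(axis=2)
    if image.ndim != 2 or image.size == 0:
        raise ParameterError("image must be a non-empty 2-D grayscale array")
    if mm_per_pixel <= 0:
        raise ParameterError("mm_per_pixel must be positive")

    sigma_px = smoothing_scale_mm / mm_per_pixel
    smooth = ndimage.gaussian_filter(image, sigma_px) if sigma_px > 0 else image
    background = float(np.quantile(smooth, background_quantile))
    deviation = np.abs(smooth - background)
    noise_sd = 1.4826 * float(np.median(deviation))
    threshold = threshold_sigmas * max(noise_sd, 1e-12)
    candidate = deviation > threshold

    labels = measure.label(candidate, connectivity=2)
    if labels.max() == 0:
        return DetectionResult(status="void")
    min_area_px = min_area_mm2 / (mm_per_pixel * mm_per_pixel)
    counts = np.bincount(labels.ravel())
    counts[0] = 0
    keep = np.nonzero(counts >= min_area_px)[0]
    if keep.size == 0:
        return DetectionResult(status="void")
    # largest pixel count; ties broken by first occurrence in row-major order
    best_count = counts[keep].max()
    tied = keep[counts[keep] == best_count]
    if tied.size == 1:
        label = int(tied[0])
    else:
        first_pos = {
            lab: int(np.flatnonzero(labels.ravel() == lab)[0]) for lab in tied
        }
        label = min(first_pos, key=first_pos.get)

    component = labels == label
    rr, cc = np.nonzero(component)
    box = BoundingBox(x0=int(cc.min()), y0=int(rr.min()),
                      x1=int(cc.max()) + 1, y1=int(rr.max()) + 1,
                      confidence=1.0)
    weights = deviation[component]
    cx_px = float(np.average(cc, weights=weights))
    cy_px = float(np.average(rr, weights=weights))
    centroid_mm = ((cx_px + 0.5) * mm_per_pixel, (cy_px + 0.5) * mm_per_pixel)
    return DetectionResult(status="found", box=box, centroid_mm=centroid_mm)


# ---------------------------------------------------------------------------
# Evaluation metrics
# ---------------------------------------------------------------------------

def iou(a: BoundingBox, b: BoundingBox) -> float:
    """Intersection over union of two half-open boxes, in [0, 1]."""
    ix = max(0.0, min(a.x1, b.x1) - max(a.x0, b.x0))
    iy = max(0.0, min(a.y1, b.y1) - max(a.y0, b.y0))
    inter = ix * iy
    union = a.area + b.area - inter
    return inter / union


def mean_average_precision(
    predictions: Sequence[Sequence[BoundingBox]],
    truths: Sequence[Sequence[BoundingBox]],
    iou_thresholds: Sequence[float] = IOU_THRESHOLDS,
) -> float:
    """Single-class mAP over an IoU-threshold grid (default 0.50:0.05:0.95).

    ``predictions[i]`` and ``truths[i]`` are the scored predicted boxes and
    ground-truth boxes of image i. At each threshold, predictions are
    matched greedily in order of descending confidence (each truth matched
    at most once, a match requires IoU >= threshold); AP is the area under
    the all-point-interpolated precision-recall curve over all images, and
    mAP is the mean over the thresholds.
    """
    if len(predictions) != len(truths):
        raise ParameterError("predictions and truths must align per image")
    n_truth = sum(len(t) for t in truths)
    if n_truth == 0:
        raise UndefinedStatisticError("mAP undefined with no ground-truth boxes")

    flat = [
        (p.confidence, img, p)
        for img, preds in enumerate(predictions)
        for p in preds
    ]
    flat.sort(key=lambda t: -t[0])
    if not flat:
        return 0.0

    aps = []
    for thr in iou_thresholds:
        matched = [np.zeros(len(t), dtype=bool) for t in truths]
        tp = np.zeros(len(flat))
        for k, (_, img, pred) in enumerate(flat):
            best_iou, best_j = 0.0, -1
            for j, truth in enumerate(truths[img]):
                if matched[img][j]:
                    continue
                o = iou(pred, truth)
                if o > best_iou:
                    best_iou, best_j = o, j
            if best_j >= 0 and best_iou >= thr:
                matched[img][best_j] = True
                tp[k] = 1.0
        cum_tp = np.cumsum(tp)
        recall = cum_tp / n_truth
        precision = cum_tp / np.arange(1, len(flat) + 1)
        # all-point interpolation: precision envelope from the right
        envelope = np.maximum.accumulate(precision[::-1])[::-1]
        recall = np.concatenate(([0.0], recall))
        envelope = np.concatenate((envelope, [envelope[-1]]))
        aps.append(float(np.sum(np.diff(recall) * envelope[1:])))
    return float(np.mean(aps))


def centroid_shift(pred_centroid_mm: tuple[float, float],
                   true_centroid_mm: tuple[float, float]) -> float:
    """Euclidean distance between two mm centroids, in micrometers."""
    dx = pred_centroid_mm[0] - true_centroid_mm[0]
    dy = pred_centroid_mm[1] - true_centroid_mm[1]
    return 1000.0 * float(np.hypot(dx, dy))


# ---------------------------------------------------------------------------
# Centroid -> stage conversion
# ---------------------------------------------------------------------------

def centroid_to_stage(centroid_mm: tuple[float, float],
                      cal: StageCalibration) -> tuple[float, float]:
    """Convert a detected centroid to X/Y stage voltages (pure affine map)."""
    return tuple(
        cal.reference_voltage[i]
        + (centroid_mm[i] + cal.webcam_to_oct_offset_mm[i]) / cal.mm_per_volt[i]
        for i in range(2)
    )


def stage_to_centroid(voltages: tuple[float, float],
                      cal: StageCalibration) -> tuple[float, float]:
    """Inverse of :func:`centroid_to_stage`."""
    return tuple(
        (voltages[i] - cal.reference_voltage[i]) * cal.mm_per_volt[i]
        - cal.webcam_to_oct_offset_mm[i]
        for i in range(2)
    )
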