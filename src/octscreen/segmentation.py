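"""B-scan tissue segmentation, segmentation metrics and augmentations.

Explant B-scans carry three characteristic nuisances: fully saturated
specular-reflection columns, smooth reflectance inhomogeneity across the
tissue, and a thin bright supporting-membrane layer below the explant that a
naive intensity threshold would happily label as tissue. The classical
segmenter here flags saturated columns before estimating a robust global
threshold, removes thin membrane-like components by an axial-extent rule,
keeps the largest remaining component, and in-paints the flagged columns by
horizontal interpolation of the mask.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional

import numpy as np
from scipy import ndimage
from skimage import filters

from .errors import ParameterError, UnsegmentableFrameError


@dataclass
class BScan:
    """One OCT cross-section: rows = depth (increasing downward), cols = lateral."""

    data: np.ndarray
    dz_um: float = 2.0
    dx_um: float = 12.0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 2 or self.data.size == 0:
            raise ParameterError("B-scan must be a non-empty 2-D grid")
        if self.dz_um <= 0 or self.dx_um <= 0:
            raise ParameterError("voxel spacings must be strictly positive")


@dataclass
class SegMetrics:
    recall: float
    precision: float
    dice: float


# ---------------------------------------------------------------------------
# Classical segmenter
# ---------------------------------------------------------------------------

def _flag_saturated_columns(img: np.ndarray, sat_fraction: float = 0.6
                            ) -> np.ndarray:
    """Columns where >= ``sat_fraction`` of pixels sit at the intensity cap.

    The cap is taken relative to the frame's intensity range so the rule is
    invariant to affine rescaling; a specular column is saturated over its
    whole depth, whereas the membrane or tissue occupies only a small
    fraction of any normal column.
    """
    lo, hi = float(img.min()), float(img.max())
    if hi <= lo:
        return np.zeros(img.shape[1], dtype=bool)
    near_cap = img >= hi - 0.05 * (hi - lo)
    return near_cap.mean(axis=0) >= sat_fraction


def segment_classical(
    bscan: BScan,
    *,
    smooth_scale: tuple[float, float] = (0.8, 2.5),
    membrane_max_thickness_um: float = 40.0,
    min_component_px: int = 16,
    max_specular_column_fraction: float = 0.5,
) -> np.ndarray:
    """Delineate the tissue in one B-scan as a {0,1} uint8 mask.

    Pipeline: (1) flag saturated columns and exclude them from threshold
    estimation; (2) Gaussian-smooth with an anisotropic kernel
    (``smooth_scale`` = (axial, lateral) sigmas in pixels; gentle axially so
    the thin gap above the membrane survives, stronger laterally where the
    tissue is homogeneous; skipped entirely on noise-free frames so exact
    two-level images segment exactly); (3) Otsu threshold over unflagged
    pixels; (4) in-paint flagged columns by horizontal interpolation between
    their unflagged neighbours, so saturated columns cannot split the tissue
    band; (5) drop components whose axial extent never exceeds
    ``membrane_max_thickness_um`` (membrane suppression); (6) keep the
    largest remaining component and fill holes.

    Raises :class:`UnsegmentableFrameError` when the flagged-column fraction
    exceeds ``max_specular_column_fraction`` (in particular when every
    column is saturated).
    """
    img = np.asarray(bscan.data, dtype=np.float64)
    flagged = _flag_saturated_columns(img)
    if flagged.mean() > max_specular_column_fraction:
        raise UnsegmentableFrameError(
            f"{flagged.mean():.0%} of columns saturated"
        )

    lo, hi = float(img.min()), float(img.max())
    if hi <= lo:  # featureless frame: nothing to segment
        return np.zeros(img.shape, dtype=np.uint8)

    # Adaptive denoising: a noise-free frame needs (and tolerates) none.
    valid = img[:, ~flagged]
    noise = float(np.median(np.abs(valid - ndimage.median_filter(
        valid, size=3))))
    if np.isscalar(smooth_scale):
        smooth_scale = (float(smooth_scale), float(smooth_scale))
    smooth = ndimage.gaussian_filter(img, smooth_scale) if noise > 0 else img

    try:
        threshold = filters.threshold_otsu(smooth[:, ~flagged])
    except ValueError:  # single-valued histogram
        return np.zeros(img.shape, dtype=np.uint8)
    mask = smooth > threshold
    if flagged.any():
        mask[:, flagged] = False
        mask = _inpaint_columns(mask, flagged)

    # Membrane suppression: remove components that are thin (in depth)
    # everywhere along their lateral extent.
    mem_px = max(1, int(round(membrane_max_thickness_um / bscan.dz_um)))
    labels, n_labels = ndimage.label(mask)
    keep_sizes = {}
    for lab in range(1, n_labels + 1):
        comp = labels == lab
        extent = comp.sum(axis=0)
        if extent.max() <= mem_px or comp.sum() < min_component_px:
            mask[comp] = False
        else:
            keep_sizes[lab] = int(comp.sum())
    if not keep_sizes:
        return np.zeros(img.shape, dtype=np.uint8)

    best = max(sorted(keep_sizes), key=lambda lab: keep_sizes[lab])
    mask = labels == best
    mask = ndimage.binary_fill_holes(mask)
    return mask.astype(np.uint8)


def _inpaint_columns(mask: np.ndarray, flagged: np.ndarray) -> np.ndarray:
    """Fill flagged columns by linear interpolation of the mask between the
    nearest unflagged columns on either side (nearest-copy at the borders)."""
    out = mask.copy().astype(np.float64)
    cols = np.arange(mask.shape[1])
    good = cols[~flagged]
    if good.size == 0:
        return mask
    for c in cols[flagged]:
        left = good[good < c]
        right = good[good > c]
        if left.size and right.size:
            l, r = left[-1], right[0]
            w = (c - l) / (r - l)
            out[:, c] = (1 - w) * mask[:, l] + w * mask[:, r]
        elif left.size:
            out[:, c] = mask[:, left[-1]]
        else:
            out[:, c] = mask[:, right[0]]
    return out >= 0.5


def segment_volume(volume: np.ndarray, dz_um: float, dx_um: float,
                   **params) -> np.ndarray:
    """Apply :func:`segment_classical` to every B-scan of a volume.

    Frames that raise :class:`UnsegmentableFrameError` yield empty masks so
    a single pathological frame cannot abort a screen.
    """
    volume = np.asarray(volume)
    if volume.ndim != 3:
        raise ParameterError("volume must be 3-D (n_bscans, axial, n_alines)")
    masks = np.zeros(volume.shape, dtype=np.uint8)
    for y in range(volume.shape[0]):
        try:
            masks[y] = segment_classical(
                BScan(volume[y], dz_um=dz_um, dx_um=dx_um), **params)
        except UnsegmentableFrameError:
            pass
    return masks


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------

def seg_metrics(pred: np.ndarray, truth: np.ndarray) -> SegMetrics:
    """Recall, precision and Dice of a predicted mask against ground truth.

    Conventions on empty masks: both empty -> all metrics 1; exactly one
    empty -> all metrics 0.
    """
    pred = np.asarray(pred).astype(bool)
    truth = np.asarray(truth).astype(bool)
    if pred.shape != truth.shape:
        raise ParameterError("pred and truth shapes differ")
    p_any, t_any = pred.any(), truth.any()
    if not p_any and not t_any:
        return SegMetrics(1.0, 1.0, 1.0)
    if not p_any or not t_any:
        return SegMetrics(0.0, 0.0, 0.0)
    tp = float(np.logical_and(pred, truth).sum())
    fp = float(pred.sum()) - tp
    fn = float(truth.sum()) - tp
    recall = tp / (tp + fn)
    precision = tp / (tp + fp)
    dice = 2 * tp / (2 * tp + fp + fn)
    return SegMetrics(recall, precision, dice)


# ---------------------------------------------------------------------------
# Augmentations (paired image/mask transforms for training-set enlargement)
# ---------------------------------------------------------------------------

def flip_h(image: np.ndarray, mask: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Mirror image and mask left-right."""
    return image[:, ::-1].copy(), mask[:, ::-1].copy()


def flip_v(image: np.ndarray, mask: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Mirror image and mask top-bottom."""
    return image[::-1, :].copy(), mask[::-1, :].copy()


def translate(image: np.ndarray, mask: np.ndarray, shift: tuple[int, int],
              fill: float = 0.0) -> tuple[np.ndarray, np.ndarray]:
    """Shift image and mask by (rows, cols) pixels, padding with ``fill``
    (image) and 0 (mask); pixels shifted off-frame are discarded."""
    out_img = np.full_like(image, fill)
    out_mask = np.zeros_like(mask)
    dy, dx = shift
    rows, cols = image.shape
    src_r = slice(max(0, -dy), min(rows, rows - dy))
    src_c = slice(max(0, -dx), min(cols, cols - dx))
    dst_r = slice(max(0, dy), min(rows, rows + dy))
    dst_c = slice(max(0, dx), min(cols, cols + dx))
    out_img[dst_r, dst_c] = image[src_r, src_c]
    out_mask[dst_r, dst_c] = mask[src_r, src_c]
    return out_img, out_mask


def adjust_contrast(image: np.ndarray, factor: float,
                    center: Optional[float] = None) -> np.ndarray:
    """Rescale image contrast about ``center`` (default: the mean)."""
    image = np.asarray(image, dtype=np.float64)
    c = float(image.mean()) if center is None else center
    return c + factor * (image - c)


def augment(image: np.ndarray, mask: np.ndarray,
            ops: Iterable[str], seed: int, n_samples: int = 1,
            max_shift_px: int = 16,
            contrast_range: tuple[float, float] = (0.8, 1.25),
            fill: float = 0.0) -> list[tuple[np.ndarray, np.ndarray]]:
    """Generate seeded random augmented (image, mask) pairs.

    ``ops`` is a subset of {"translate", "contrast", "flip_h", "flip_v"}.
    Geometric operations are applied identically to image and mask;
    contrast touches the image only.
    """
    ops = list(ops)
    known = {"translate", "contrast", "flip_h", "flip_v"}
    unknown = set(ops) - known
    if unknown:
        raise ParameterError(f"unknown augmentation ops: {sorted(unknown)}")
    rng = np.random.default_rng(seed)
    pairs = []
    for _ in range(n_samples):
        img, msk = np.array(image, dtype=np.float64), np.array(mask)
        for op in ops:
            if op == "translate":
                dy = int(rng.integers(-max_shift_px, max_shift_px + 1))
                dx = int(rng.integers(-max_shift_px, max_shift_px + 1))
                img, msk = translate(img, msk, (dy, dx), fill=fill)
            elif op == "contrast":
                factor = float(rng.uniform(*contrast_range))
                img = adjust_contrast(img, factor)
            elif op == "flip_h" and rng.random() < 0.5:
                img, msk = flip_h(img, msk)
            elif op == "flip_v" and rng.random() < 0.5:
                img, msk = flip_v(img, msk)
        pairs.append((img, msk))
    return pairs
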