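"""Optimal axial (Z-motor) position selection from a depth sweep.

During acquisition the Z stage is swept while B-scans are recorded; the
stage position whose B-scan has the greatest mean intensity is taken as the
optimal optical path length and used to trigger volume recording. In
practice the sweep can be restricted to a narrow window, or skipped entirely
after the first sample of a plate (handled at the pipeline level).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .errors import ParameterError


@dataclass
class DepthStack:
    """An ordered sweep of candidate stage positions and their B-scans."""

    positions: np.ndarray  # strictly increasing stage coordinates
    frames: Sequence[np.ndarray]  # one 2-D intensity grid per position
    restrict_range: Optional[tuple[float, float]] = None

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=np.float64)
        if self.positions.ndim != 1 or len(self.positions) < 1:
            raise ParameterError("positions must be a non-empty 1-D array")
        if len(self.positions) != len(self.frames):
            raise ParameterError("positions and frames length mismatch")
        if len(self.positions) > 1 and not np.all(np.diff(self.positions) > 0):
            raise ParameterError("positions must be strictly increasing")


def mean_frame_intensity(frame: np.ndarray) -> float:
    """Arithmetic mean over all pixels of a B-scan."""
    frame = np.asarray(frame)
    if frame.size == 0:
        raise ParameterError("empty frame")
    return float(frame.mean(dtype=np.float64))


def find_optimal_depth(stack: DepthStack) -> tuple[float, int]:
    """Return (stage position, index) of the brightest frame in the sweep.

    Brightness is the mean intensity over the whole B-scan. If the stack
    carries a ``restrict_range`` (lo, hi), only positions inside that closed
    interval are considered (indices are still global). Ties are broken by
    the lowest index.
    """
    lo_idx, hi_idx = 0, len(stack.positions)
    if stack.restrict_range is not None:
        lo, hi = stack.restrict_range
        inside = np.nonzero((stack.positions >= lo) & (stack.positions <= hi))[0]
        if inside.size == 0:
            raise ParameterError("restriction window contains no positions")
        lo_idx, hi_idx = int(inside[0]), int(inside[-1]) + 1
    means = [mean_frame_intensity(f) for f in stack.frames[lo_idx:hi_idx]]
    best = lo_idx + int(np.argmax(means))  # argmax returns the first maximum
    return float(stack.positions[best]), best
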