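"""Uncaging-target relocation and depth-dependent stimulus parameters.

Photolysis must land on the spine membrane: immediately before each
stimulus the frame is binarized, the perimeter of the foreground
objects is extracted, and the stored target is moved to the nearest
perimeter pixel. Pulse energy is scaled with tissue depth (deeper
spines scatter more excitation light), linearly interpolating pulse
duration between 4 and 8 ms and laser power between 3.5 and 4.0 mW over
the configured depth range; the stimulus train is 30 pulses at 1 Hz.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .core import as_image

__all__ = [
    "TargetPoint",
    "UncagingParams",
    "SpineLostError",
    "binarize",
    "perimeter",
    "perimeter_mask",
    "relocate_target",
    "uncaging_params_for_depth",
]


@dataclass(frozen=True)
class TargetPoint:
    """Integer pixel coordinates of an uncaging target."""

    row: int
    col: int

    def as_tuple(self) -> tuple[int, int]:
        return self.row, self.col


@dataclass(frozen=True)
class UncagingParams:
    """One uncaging train: power, pulse duration, pulse count and rate."""

    power_mW: float
    pulse_ms: float
    n_pulses: int = 30
    rate_Hz: float = 1.0


class SpineLostError(RuntimeError):
    """No foreground above threshold: the spine left the frame or faded."""


def binarize(image, threshold: float, relative: bool = False) -> np.ndarray:
    """Boolean mask of pixels at or above threshold.

    With ``relative=True`` the threshold is a fraction of the frame
    maximum instead of an absolute intensity; a frame with no signal at
    all (max = 0) then yields an empty mask rather than selecting
    everything.
    """
    img = as_image(image)
    if not np.isfinite(threshold):
        raise ValueError("threshold must be finite")
    if relative:
        peak = float(img.max())
        if peak <= 0.0:
            return np.zeros_like(img, dtype=bool)
        return img >= threshold * peak
    return img >= threshold


def perimeter_mask(mask: np.ndarray) -> np.ndarray:
    """Foreground pixels with a 4-neighbor that is background or off-frame.

    4-connectivity membership yields a closed 8-connected boundary curve
    for the relocated target to land on.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.ndim != 2:
        raise ValueError("mask must be 2D")
    if not mask.any():
        raise SpineLostError("empty mask: no foreground above threshold")
    structure = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool)
    interior = ndimage.binary_erosion(mask, structure=structure,
                                      border_value=0)
    return mask & ~interior


def perimeter(mask: np.ndarray) -> list[TargetPoint]:
    """Perimeter pixels of a binary mask, in row-major order."""
    rows, cols = np.nonzero(perimeter_mask(mask))
    return [TargetPoint(int(r), int(c)) for r, c in zip(rows, cols)]


def relocate_target(image, threshold: float, target: TargetPoint,
                    relative: bool = False) -> TargetPoint:
    """Move a target to the closest perimeter point of the thresholded frame.

    Euclidean distance; ties broken by smallest row, then smallest
    column. Raises :class:`SpineLostError` when nothing exceeds the
    threshold (the session runner treats this as a lost spine).
    """
    img = as_image(image)
    h, w = img.shape
    if not (0 <= target.row < h and 0 <= target.col < w):
        raise ValueError(f"target {target} outside {h}x{w} frame")
    boundary = perimeter_mask(binarize(img, threshold, relative=relative))
    rows, cols = np.nonzero(boundary)  # row-major: natural tie order
    d2 = (rows - target.row) ** 2 + (cols - target.col) ** 2
    i = int(np.argmin(d2))  # argmin keeps the first (smallest row, col) tie
    return TargetPoint(int(rows[i]), int(cols[i]))


def uncaging_params_for_depth(depth_um: float, depth_min_um: float,
                              depth_max_um: float) -> UncagingParams:
    """Depth-modulated uncaging parameters.

    Linearly interpolates (4 ms, 3.5 mW) at ``depth_min_um`` to
    (8 ms, 4.0 mW) at ``depth_max_um``; depths outside the range are
    clamped. The train is fixed at 30 pulses, 1 Hz.
    """
    if not depth_min_um < depth_max_um:
        raise ValueError("degenerate depth range")
    f = (np.clip(depth_um, depth_min_um, depth_max_um) - depth_min_um) / (
        depth_max_um - depth_min_um
    )
    return UncagingParams(
        power_mW=float(3.5 + 0.5 * f),
        pulse_ms=float(4.0 + 4.0 * f),
        n_pulses=30,
        rate_Hz=1.0,
    )
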