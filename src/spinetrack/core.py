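"""Shared data containers: images, rectangular ROIs and Z-stacks.

Images are plain 2D numpy arrays of non-negative finite intensities
(any integer or float dtype; computations are performed in float64).
A :class:`ZStack` bundles the ordered slices of one axial sweep with
their physical Z positions and is the unit on which autofocus operates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["RectROI", "ZStack", "as_image"]


def as_image(pixels) -> np.ndarray:
    """Validate and convert an image to a float64 2D array.

    Raises ``ValueError`` for non-2D input, non-finite or negative
    intensities, or empty axes.
    """
    arr = np.asarray(pixels, dtype=np.float64)
    if arr.ndim != 2:
        raise ValueError(f"image must be 2D, got shape {arr.shape}")
    if arr.shape[0] < 1 or arr.shape[1] < 1:
        raise ValueError("image must have height, width >= 1")
    if not np.all(np.isfinite(arr)):
        raise ValueError("image contains non-finite values")
    if np.any(arr < 0):
        raise ValueError("image contains negative intensities")
    return arr


@dataclass(frozen=True)
class RectROI:
    """Axis-aligned rectangular region, half-open extent, 0-based.

    ``row0``/``col0`` index the top-left pixel; ``height``/``width``
    give the extent in pixels so the ROI covers rows
    ``row0 .. row0+height-1`` and columns ``col0 .. col0+width-1``.
    """

    row0: int
    col0: int
    height: int
    width: int

    def __post_init__(self):
        if self.row0 < 0 or self.col0 < 0:
            raise ValueError("ROI origin must be non-negative")
        if self.height < 1 or self.width < 1:
            raise ValueError("ROI extent must be positive")
        if self.height * self.width < 4:
            raise ValueError("ROI area must be at least 4 pixels")

    def validate_in(self, shape: tuple[int, int]) -> None:
        h, w = shape
        if self.row0 + self.height > h or self.col0 + self.width > w:
            raise ValueError(
                f"ROI {self} exceeds image bounds {h}x{w}"
            )

    def extract(self, image: np.ndarray) -> np.ndarray:
        self.validate_in(image.shape)
        return image[
            self.row0 : self.row0 + self.height,
            self.col0 : self.col0 + self.width,
        ]


@dataclass
class ZStack:
    """Ordered 2D slices at strictly increasing, uniformly spaced Z.

    ``slices`` is a 3D array (n_slices, height, width); ``z_positions``
    holds the focal position of each slice in micrometres.
    """

    slices: np.ndarray
    z_positions: np.ndarray = field(default=None)

    _Z_UNIFORMITY_TOL = 1e-9  # um

    def __post_init__(self):
        self.slices = np.asarray(self.slices, dtype=np.float64)
        if self.slices.ndim != 3:
            raise ValueError("stack must be 3D (n_slices, height, width)")
        n = self.slices.shape[0]
        if n < 2:
            raise ValueError("stack needs at least 2 slices")
        if self.z_positions is None:
            self.z_positions = np.arange(n, dtype=np.float64)
        self.z_positions = np.asarray(self.z_positions, dtype=np.float64)
        if self.z_positions.shape != (n,):
            raise ValueError("one z position per slice required")
        dz = np.diff(self.z_positions)
        if np.any(dz <= 0):
            raise ValueError("z positions must be strictly increasing")
        if np.ptp(dz) > self._Z_UNIFORMITY_TOL:
            raise ValueError("z spacing must be uniform")

    @property
    def n_slices(self) -> int:
        return self.slices.shape[0]

    @property
    def step_um(self) -> float:
        return float(self.z_positions[1] - self.z_positions[0])

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.slices.shape[1], self.slices.shape[2]

    def __len__(self) -> int:
        return self.n_slices

    def __iter__(self):
        return iter(self.slices)
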