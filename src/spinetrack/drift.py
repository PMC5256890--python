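"""Lateral drift estimation by Fourier cross-correlation.

The estimator computes the 2D DFT of the reference and the newly
acquired frame, multiplies one transform by the complex conjugate of
the other, inverse-transforms, moves the zero-lag corners to the array
center, and reads the displacement off the location of the correlation
peak minus the center index. The result is the integer circular
displacement of the new frame relative to the reference; negating it
gives the scan-shift that re-centers the specimen.

Raw cross-correlation (no spectral whitening) is the default; optional
mean subtraction is available for bright, slowly varying backgrounds
where the DC term would otherwise dominate the peak.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import fft as sp_fft

from .core import as_image

__all__ = ["ShiftEstimate", "estimate_shift", "corrective_shift"]


@dataclass(frozen=True)
class ShiftEstimate:
    """Integer lateral displacement (pixels) of a frame vs a reference.

    ``peak_value`` is the maximum of the circular cross-correlation
    surface (arbitrary units, useful as a match-quality score).
    """

    d_row: int
    d_col: int
    peak_value: float = 0.0

    def as_tuple(self) -> tuple[int, int]:
        return self.d_row, self.d_col

    def __neg__(self) -> "ShiftEstimate":
        return ShiftEstimate(-self.d_row, -self.d_col, self.peak_value)


def estimate_shift(reference, new, subtract_mean: bool = False) -> ShiftEstimate:
    """Estimate the circular displacement of ``new`` relative to ``reference``.

    Both images must share dimensions and be non-constant (the
    correlation peak of a constant image is undefined up to ties).
    Displacements are integer pixels; ties at the correlation peak are
    broken toward the smallest row, then the smallest column.
    """
    ref = as_image(reference)
    img = as_image(new)
    if ref.shape != img.shape:
        raise ValueError(f"shape mismatch: {ref.shape} vs {img.shape}")
    if np.ptp(ref) == 0 or np.ptp(img) == 0:
        raise ValueError("constant image: correlation peak undefined")
    if subtract_mean:
        ref = ref - ref.mean()
        img = img - img.mean()

    # correlation surface peaks at the lag aligning `new` onto `reference`
    corr = sp_fft.ifft2(sp_fft.fft2(img) * np.conj(sp_fft.fft2(ref))).real
    corr = sp_fft.fftshift(corr)
    peak = float(corr.max())
    # unravel_index of argmax = smallest row then column among exact ties
    r, c = np.unravel_index(int(np.argmax(corr)), corr.shape)
    h, w = corr.shape
    return ShiftEstimate(int(r - h // 2), int(c - w // 2), peak)


def corrective_shift(est: ShiftEstimate) -> tuple[int, int]:
    """Scan-window shift compensating an estimated drift (its negation)."""
    return -est.d_row, -est.d_col
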