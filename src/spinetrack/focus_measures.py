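"""Registry of focus-measure operators.

Each operator maps a 2D image (optionally restricted to a rectangular
ROI) to a scalar focus value with the uniform convention *higher =
sharper*, so a plain argmax over a focus curve selects the best focal
plane regardless of the operator chosen.

The registry covers 27 operators: 25 measures from the shape-from-focus
literature (gradient-, Laplacian-, statistics-, histogram-, DCT- and
wavelet-free transform-based families) plus two maximum-intensity
measures, Maximum Brightness (``BRGT``, the maximum pixel intensity)
and Maximum Brightness Gradient (``MGRD``, the maximum gradient
magnitude, central differences in both axes).

All operators compute in float64 regardless of the input integer depth
and are deterministic. Per-operator defaults (window sizes, thresholds,
Gaussian scales, DCT block sizes) are stored in the registry and can be
overridden per call via keyword arguments to :func:`compute_focus`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy import ndimage
from scipy.fft import dctn

from .core import RectROI, as_image

__all__ = ["FocusOperator", "list_operators", "get_operator", "compute_focus"]

_EPS = 1e-12


# ---------------------------------------------------------------------------
# small helpers

def _hist256(img: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """256-bin normalized histogram over the image's intensity range.

    Returns (probabilities, bin centers on a 0..1 normalized axis).
    """
    lo, hi = float(img.min()), float(img.max())
    if hi - lo < _EPS:
        p = np.zeros(256)
        p[0] = 1.0
        return p, (np.arange(256) + 0.5) / 256.0
    counts, edges = np.histogram(img, bins=256, range=(lo, hi))
    p = counts / counts.sum()
    centers = (edges[:-1] + edges[1:]) / 2.0
    centers = (centers - lo) / (hi - lo)
    return p, centers


def _conv(img: np.ndarray, kernel) -> np.ndarray:
    # true convolution (kernel flipped), replicated borders
    return ndimage.convolve(img, np.asarray(kernel, dtype=np.float64),
                            mode="nearest")


def _local_mean(img: np.ndarray, size: int) -> np.ndarray:
    return ndimage.uniform_filter(img, size=size, mode="nearest")


def _local_variance(img: np.ndarray, size: int) -> np.ndarray:
    m = _local_mean(img, size)
    m2 = _local_mean(img * img, size)
    return np.clip(m2 - m * m, 0.0, None)


def _gauss_deriv(img: np.ndarray, sigma: float) -> tuple[np.ndarray, np.ndarray]:
    gr = ndimage.gaussian_filter(img, sigma, order=(1, 0), mode="nearest")
    gc = ndimage.gaussian_filter(img, sigma, order=(0, 1), mode="nearest")
    return gr, gc


def _block_dct_energies(img: np.ndarray, block: int) -> tuple[np.ndarray, np.ndarray]:
    """Per-block (DC^2, AC energy) for non-overlapping block x block tiles."""
    b = min(block, img.shape[0], img.shape[1])
    h = (img.shape[0] // b) * b
    w = (img.shape[1] // b) * b
    tiles = img[:h, :w].reshape(h // b, b, w // b, b).transpose(0, 2, 1, 3)
    coeffs = dctn(tiles, axes=(2, 3), norm="ortho")
    sq = coeffs * coeffs
    total = sq.sum(axis=(2, 3))
    dc = sq[:, :, 0, 0]
    return dc.ravel(), (total - dc).ravel()


# ---------------------------------------------------------------------------
# operator implementations — each takes a float64 2D array, returns a float

def _acmo(img):
    """Absolute central moment of the gray-level histogram."""
    p, u = _hist256(img)
    mu = float(np.sum(u * p))
    return float(np.sum(np.abs(u - mu) * p))


def _bren(img):
    """Brenner's measure: mean of the larger squared 2-step difference."""
    dv = np.zeros_like(img)
    dh = np.zeros_like(img)
    dv[:-2, :] = img[2:, :] - img[:-2, :]
    dh[:, :-2] = img[:, 2:] - img[:, :-2]
    return float(np.mean(np.maximum(dv * dv, dh * dh)))


def _cont(img):
    """Image contrast: mean absolute difference to the 8 neighbors."""
    total = np.zeros_like(img)
    for dr in (-1, 0, 1):
        for dc in (-1, 0, 1):
            if dr == 0 and dc == 0:
                continue
            shifted = np.roll(np.roll(img, dr, axis=0), dc, axis=1)
            total += np.abs(img - shifted)
    return float(np.mean(total))


_M1 = np.array([[-1.0, 0.0, 1.0]] * 3)
_M2 = np.array([[1.0, 0.0, 1.0]] * 3)


def _curv(img):
    """Surface-curvature measure from local quadratic fits."""
    p0 = _conv(img, _M1) / 6.0
    p1 = _conv(img, _M1.T) / 6.0
    a = _conv(img, _M2)
    b = _conv(img, _M2.T)
    p2 = 0.3 * a - 0.2 * b
    p3 = -0.2 * a + 0.3 * b
    return float(np.mean(np.abs(p0) + np.abs(p1) + np.abs(p2) + np.abs(p3)))


def _dcte(img, block=8):
    """Mean AC energy of blockwise orthonormal DCT-II coefficients."""
    _, ac = _block_dct_energies(img, block)
    return float(np.mean(ac))


def _dctr(img, block=8):
    """Mean blockwise ratio of total DCT energy to DC energy."""
    dc, ac = _block_dct_energies(img, block)
    return float(np.mean((dc + ac) / (dc + _EPS)))


def _gder(img, sigma=1.0):
    """Gaussian-derivative energy at scale sigma."""
    gr, gc = _gauss_deriv(img, sigma)
    return float(np.mean(gr * gr + gc * gc))


def _glva(img):
    """Gray-level variance."""
    return float(np.var(img))


def _gllv(img, size=7):
    """Variance of the local gray-level variance (size x size windows)."""
    return float(np.var(_local_variance(img, size)))


def _glvn(img):
    """Normalized variance: variance over mean intensity."""
    m = float(np.mean(img))
    if m < _EPS:
        return 0.0
    return float(np.var(img) / m)


def _first_diffs(img):
    dv = np.zeros_like(img)
    dh = np.zeros_like(img)
    dv[:-1, :] = img[1:, :] - img[:-1, :]
    dh[:, :-1] = img[:, 1:] - img[:, :-1]
    return dv, dh


def _grae(img):
    """Energy of the first-difference gradient."""
    dv, dh = _first_diffs(img)
    return float(np.mean(dv * dv + dh * dh))


def _grat(img, threshold=0.0):
    """Thresholded absolute gradient (mean over supra-threshold pixels)."""
    dv, dh = _first_diffs(img)
    g = np.maximum(np.abs(dv), np.abs(dh))
    g = np.where(g >= threshold, g, 0.0)
    n = int(np.count_nonzero(g))
    if n == 0:
        return 0.0
    return float(g.sum() / n)


def _gras(img):
    """Squared horizontal first-difference gradient."""
    dh = img[:, 1:] - img[:, :-1]
    return float(np.mean(dh * dh))


def _helm(img, size=7):
    """Helmli & Scherer's mean-ratio measure."""
    u = _local_mean(img, size)
    r = np.ones_like(img)
    nz = img > _EPS
    r[nz] = u[nz] / img[nz]
    fm = np.where(r > _EPS, 1.0 / np.where(r > _EPS, r, 1.0), 1.0)
    above = u > img
    fm[above] = r[above]
    return float(np.mean(fm))


def _hise(img):
    """Shannon entropy of the gray-level histogram."""
    p, _ = _hist256(img)
    nz = p > 0
    return float(-np.sum(p[nz] * np.log2(p[nz])))


def _hisr(img):
    """Histogram (intensity) range."""
    return float(img.max() - img.min())


_LAP4 = np.array([[0.0, 1.0, 0.0], [1.0, -4.0, 1.0], [0.0, 1.0, 0.0]])


def _lape(img):
    """Energy of the 4-neighbor Laplacian."""
    lap = _conv(img, _LAP4)
    return float(np.mean(lap * lap))


_LX = np.array([[-1.0, 2.0, -1.0]])


def _lapm(img):
    """Modified Laplacian: mean absolute axial second differences."""
    lx = _conv(img, _LX)
    ly = _conv(img, _LX.T)
    return float(np.mean(np.abs(lx) + np.abs(ly)))


def _lapv(img):
    """Variance of the Laplacian response."""
    lap = _conv(img, _LAP4)
    return float(np.var(lap))


_D1 = np.array([[1.0, 0.0, 0.0], [0.0, -2.0, 0.0], [0.0, 0.0, 1.0]]) / np.sqrt(2)
_D2 = np.array([[0.0, 0.0, 1.0], [0.0, -2.0, 0.0], [1.0, 0.0, 0.0]]) / np.sqrt(2)


def _lapd(img):
    """Diagonal Laplacian: modified Laplacian plus diagonal terms."""
    lx = _conv(img, _LX)
    ly = _conv(img, _LX.T)
    d1 = _conv(img, _D1)
    d2 = _conv(img, _D2)
    return float(np.mean(np.abs(lx) + np.abs(ly) + np.abs(d1) + np.abs(d2)))


def _sfil(img, sigma=1.0, n_orientations=4):
    """Steerable-filter measure: max oriented Gaussian-derivative response."""
    gr, gc = _gauss_deriv(img, sigma)
    best = np.zeros_like(img)
    for k in range(n_orientations):
        theta = np.pi * k / n_orientations
        resp = np.abs(np.cos(theta) * gc + np.sin(theta) * gr)
        np.maximum(best, resp, out=best)
    return float(np.mean(best * best))


def _sfrq(img):
    """Spatial frequency: RMS of row and column first differences."""
    dv, dh = _first_diffs(img)
    return float(np.sqrt(np.mean(dv * dv) + np.mean(dh * dh)))


def _sobel(img):
    gr = ndimage.sobel(img, axis=0, mode="nearest")
    gc = ndimage.sobel(img, axis=1, mode="nearest")
    return gr, gc


def _teng(img):
    """Tenengrad: mean squared Sobel gradient magnitude."""
    gr, gc = _sobel(img)
    return float(np.mean(gr * gr + gc * gc))


def _tenv(img):
    """Tenengrad variance."""
    gr, gc = _sobel(img)
    return float(np.var(gr * gr + gc * gc))


def _vola(img):
    """Vollath's autocorrelation measure (F4)."""
    i1 = img.copy()
    i1[:-1, :] = img[1:, :]
    i2 = img.copy()
    i2[:-2, :] = img[2:, :]
    return float(np.mean(img * (i1 - i2)))


def _brgt(img):
    """Maximum Brightness: the maximum pixel intensity."""
    return float(img.max())


def _mgrd(img):
    """Maximum Brightness Gradient: max central-difference gradient magnitude."""
    gr, gc = np.gradient(img)
    return float(np.sqrt(gr * gr + gc * gc).max())


# ---------------------------------------------------------------------------
# registry

@dataclass(frozen=True)
class FocusOperator:
    """A registered focus-measure operator.

    ``higher_is_sharper`` records the literature convention; when False
    the registry negates the raw value so that the public contract
    (higher = sharper) holds uniformly. ``defaults`` are the tunable
    parameters forwarded to the implementation; ``min_size`` is the
    smallest image/ROI side the operator's neighborhood supports.
    """

    id: str
    name: str
    func: Callable[..., float]
    higher_is_sharper: bool = True
    defaults: dict = field(default_factory=dict)
    min_size: int = 3


_REGISTRY: dict[str, FocusOperator] = {}


def _register(op_id, name, func, *, defaults=None, min_size=3,
              higher_is_sharper=True):
    _REGISTRY[op_id] = FocusOperator(
        id=op_id, name=name, func=func,
        higher_is_sharper=higher_is_sharper,
        defaults=dict(defaults or {}), min_size=min_size,
    )


_register("ACMO", "Absolute central moment", _acmo, min_size=2)
_register("BREN", "Brenner's focus measure", _bren)
_register("CONT", "Image contrast", _cont)
_register("CURV", "Image curvature", _curv)
_register("DCTE", "DCT energy measure", _dcte, defaults={"block": 8}, min_size=4)
_register("DCTR", "DCT energy ratio", _dctr, defaults={"block": 8}, min_size=4)
_register("GDER", "Gaussian derivative", _gder, defaults={"sigma": 1.0})
_register("GLVA", "Gray-level variance", _glva, min_size=2)
_register("GLLV", "Gray-level local variance", _gllv, defaults={"size": 7})
_register("GLVN", "Gray-level variance normalized", _glvn, min_size=2)
_register("GRAE", "Energy of gradient", _grae, min_size=2)
_register("GRAT", "Thresholded gradient", _grat, defaults={"threshold": 0.0},
          min_size=2)
_register("GRAS", "Squared gradient", _gras, min_size=2)
_register("HELM", "Helmli's measure", _helm, defaults={"size": 7})
_register("HISE", "Histogram entropy", _hise, min_size=2)
_register("HISR", "Histogram range", _hisr, min_size=2)
_register("LAPE", "Energy of Laplacian", _lape)
_register("LAPM", "Modified Laplacian", _lapm)
_register("LAPV", "Variance of Laplacian", _lapv)
_register("LAPD", "Diagonal Laplacian", _lapd)
_register("SFIL", "Steerable filters-based", _sfil,
          defaults={"sigma": 1.0, "n_orientations": 4})
_register("SFRQ", "Spatial frequency", _sfrq, min_size=2)
_register("TENG", "Tenengrad", _teng)
_register("TENV", "Tenengrad variance", _tenv)
_register("VOLA", "Vollath's correlation-based", _vola)
_register("BRGT", "Maximum Brightness", _brgt, min_size=2)
_register("MGRD", "Maximum Brightness Gradient", _mgrd, min_size=2)


def list_operators() -> frozenset[str]:
    """Return the ids of all registered focus operators."""
    return frozenset(_REGISTRY)


def get_operator(op_id: str) -> FocusOperator:
    """Look up a registered operator by its id."""
    try:
        return _REGISTRY[op_id]
    except KeyError:
        raise KeyError(
            f"unknown focus operator {op_id!r}; "
            f"known: {sorted(_REGISTRY)}"
        ) from None


def compute_focus(image, op, roi: RectROI | None = None, **params) -> float:
    """Evaluate a focus operator on an image or ROI.

    Parameters
    ----------
    image : 2D array-like of non-negative intensities
    op : str or FocusOperator
    roi : optional RectROI restricting the evaluation
    **params : operator-specific overrides of the registered defaults

    Returns a finite scalar with higher = sharper.
    """
    spec = op if isinstance(op, FocusOperator) else get_operator(op)
    img = as_image(image)
    if roi is not None:
        img = roi.extract(img)
    if min(img.shape) < spec.min_size:
        raise ValueError(
            f"{spec.id} needs at least {spec.min_size}x{spec.min_size} "
            f"pixels, got {img.shape[0]}x{img.shape[1]}"
        )
    kwargs = dict(spec.defaults)
    unknown = set(params) - set(kwargs)
    if unknown:
        raise TypeError(f"{spec.id} got unknown parameters {sorted(unknown)}")
    kwargs.update(params)
    value = float(spec.func(img, **kwargs))
    if not np.isfinite(value):
        raise ArithmeticError(f"{spec.id} produced a non-finite focus value")
    return value if spec.higher_is_sharper else -value
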