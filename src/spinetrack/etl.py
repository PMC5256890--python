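"""Electrically tunable lens (ETL) calibration math.

An ETL refocuses without moving the objective or stage: its focal
power, and hence the axial position Z of the imaged plane, follows the
drive current (0-300 mA for the supported device class). Calibration
collects (control, Z) pairs by stepping a Z motor and autofocusing with
the ETL alone, then fits either a straight line or a polynomial to
Z(control). The fitted model is inverted to place the focal plane at a
requested Z, and composed per scanline to synthesize the control
waveform for tilted-plane imaging, where the ETL is driven in phase
with the slow-scanning galvanometer.

The tilt is parameterized as a Z increment per scanline rather than an
angle (an angle form has a tangent singularity as the tilt approaches
90 degrees; dZ/line is well-posed and maps directly to the per-line
control update). Only the mapping math lives here — no device I/O.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.optimize import brentq

__all__ = [
    "CalibrationPoint",
    "CalibrationModel",
    "TiltWaveform",
    "run_calibration",
    "fit_calibration",
    "tilt_waveform",
    "CONTROL_RANGE_mA",
]

CONTROL_RANGE_mA = (0.0, 300.0)

_ROUNDTRIP_TOL_UM = 1e-6
_MONOTONIC_SAMPLES = 512


@dataclass(frozen=True)
class CalibrationPoint:
    """One calibration sample: drive current (mA) and measured focal Z (um)."""

    control_value: float
    z_um: float

    def __post_init__(self):
        lo, hi = CONTROL_RANGE_mA
        if not lo <= self.control_value <= hi:
            raise ValueError(
                f"control {self.control_value} mA outside device range {CONTROL_RANGE_mA}"
            )


@dataclass
class CalibrationModel:
    """Fitted control->Z mapping, linear or polynomial.

    ``coefficients`` are in numpy.polynomial order (lowest degree
    first). The model is only valid where the fitted curve is strictly
    monotonic; this is verified at fit time over the control range.
    """

    kind: str  # "linear" | "polynomial"
    coefficients: np.ndarray
    control_range: tuple[float, float]
    z_range: tuple[float, float] = field(default=None)
    residuals: np.ndarray = field(default=None)

    def __post_init__(self):
        self.coefficients = np.asarray(self.coefficients, dtype=np.float64)
        if self.kind not in ("linear", "polynomial"):
            raise ValueError("kind must be 'linear' or 'polynomial'")
        lo, hi = self.control_range
        if not lo < hi:
            raise ValueError("degenerate control range")
        grid = np.linspace(lo, hi, _MONOTONIC_SAMPLES)
        z = self._poly(grid)
        dz = np.diff(z)
        if not (np.all(dz > 0) or np.all(dz < 0)):
            raise ValueError("fitted curve is not strictly monotonic over range")
        self._increasing = bool(dz[0] > 0)
        zr = (float(min(z[0], z[-1])), float(max(z[0], z[-1])))
        if self.z_range is None:
            self.z_range = zr

    def _poly(self, c):
        return np.polynomial.polynomial.polyval(c, self.coefficients)

    @property
    def degree(self) -> int:
        return len(self.coefficients) - 1

    def z_for_control(self, control: float) -> float:
        lo, hi = self.control_range
        if not lo <= control <= hi:
            raise ValueError(f"control {control} outside valid range ({lo}, {hi})")
        return float(self._poly(control))

    def control_for_z(self, z_um: float) -> float:
        """Invert the fit: drive current that focuses at ``z_um``.

        Root-finding on the monotonic fitted curve; round-trips through
        z_for_control to within 1e-6 um.
        """
        lo_z, hi_z = self.z_range
        if not lo_z - _ROUNDTRIP_TOL_UM <= z_um <= hi_z + _ROUNDTRIP_TOL_UM:
            raise ValueError(f"z {z_um} um outside calibrated range {self.z_range}")
        lo, hi = self.control_range
        if len(self.coefficients) == 2:  # exact linear inverse
            b, a = self.coefficients
            return float(np.clip((z_um - b) / a, lo, hi))
        f = lambda c: self._poly(c) - z_um
        flo, fhi = f(lo), f(hi)
        if flo == 0.0:
            return float(lo)
        if fhi == 0.0:
            return float(hi)
        return float(brentq(f, lo, hi, xtol=1e-12, rtol=8.9e-16))

    def to_json(self) -> str:
        return json.dumps(
            {
                "kind": self.kind,
                "coefficients": self.coefficients.tolist(),
                "control_range": list(self.control_range),
                "z_range": list(self.z_range),
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "CalibrationModel":
        d = json.loads(text)
        return cls(
            kind=d["kind"],
            coefficients=np.asarray(d["coefficients"]),
            control_range=tuple(d["control_range"]),
            z_range=tuple(d["z_range"]),
        )


def run_calibration(z_steps: Sequence[float],
                    etl_autofocus: Callable[[float], float],
                    log: list | None = None) -> list[CalibrationPoint]:
    """Collect calibration points by stepping Z and ETL-autofocusing.

    ``etl_autofocus(z)`` returns the drive current that brings the
    plane at motor position ``z`` into focus (in simulation, the
    virtual microscope's ETL response). A step where autofocus raises
    is skipped and recorded in ``log``; at least two distinct steps
    must survive.
    """
    z_steps = list(z_steps)
    if len(set(z_steps)) < 2:
        raise ValueError("need at least 2 distinct z steps")
    points = []
    for z in z_steps:
        try:
            control = float(etl_autofocus(z))
        except Exception as exc:  # autofocus failure at this step
            if log is not None:
                log.append((z, f"autofocus failed: {exc}"))
            continue
        points.append(CalibrationPoint(control_value=control, z_um=float(z)))
    if len({p.control_value for p in points}) < 2:
        raise ValueError("calibration underdetermined: <2 usable points")
    return points


def fit_calibration(points: Sequence[CalibrationPoint],
                    kind: str = "linear", degree: int = 3) -> CalibrationModel:
    """Least-squares fit of Z(control), linear or polynomial (default cubic).

    Requires at least degree+1 points; the fitted curve must be
    strictly monotonic over the spanned control range.
    """
    controls = np.array([p.control_value for p in points], dtype=np.float64)
    zs = np.array([p.z_um for p in points], dtype=np.float64)
    d = 1 if kind == "linear" else int(degree)
    if kind not in ("linear", "polynomial"):
        raise ValueError("kind must be 'linear' or 'polynomial'")
    if len(points) < d + 1:
        raise ValueError(f"degree-{d} fit needs >= {d + 1} points, got {len(points)}")
    coeffs = np.polynomial.polynomial.polyfit(controls, zs, deg=d)
    model = CalibrationModel(
        kind=kind,
        coefficients=coeffs,
        control_range=(float(controls.min()), float(controls.max())),
    )
    model.residuals = zs - np.polynomial.polynomial.polyval(controls, coeffs)
    return model


@dataclass
class TiltWaveform:
    """Per-scanline ETL control values realizing a tilted image plane."""

    control_values: np.ndarray
    z_center_um: float
    dz_per_line_um: float

    def to_csv(self, path) -> None:
        import pandas as pd

        pd.DataFrame(
            {
                "line": np.arange(len(self.control_values)),
                "control_mA": self.control_values,
            }
        ).to_csv(path, index=False)


def tilt_waveform(model: CalibrationModel, z_center_um: float,
                  dz_per_line_um: float, n_lines: int) -> TiltWaveform:
    """Control waveform for a plane tilted by ``dz_per_line_um`` per line.

    Line ``i`` (of ``n_lines``) focuses at
    ``z_center + (i - (n_lines-1)/2) * dz_per_line``; every line's Z
    must fall inside the calibrated range or the call fails.
    """
    if n_lines < 1:
        raise ValueError("n_lines must be >= 1")
    i = np.arange(n_lines, dtype=np.float64)
    z_lines = z_center_um + (i - (n_lines - 1) / 2.0) * dz_per_line_um
    controls = np.array([model.control_for_z(z) for z in z_lines])
    return TiltWaveform(control_values=controls, z_center_um=z_center_um,
                        dz_per_line_um=dz_per_line_um)
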