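"""Spine/dendrite volume quantification from time-lapse Z-stacks.

For each time point, all Z slices are summed into one projection;
integrated fluorescence inside hand-drawn ROIs — ovals for spines,
polygons for dendrite segments — is the "volume" readout. Each object's
trace is standardized to its own pre-uncaging mean, so 1.0 is baseline.
Two windows summarize the response to uncaging at t = 0: the transient
phase (1-3 min) and the sustained phase (26-30 min). Group statistics
compare stimulated and adjacent spines against the dendrite control
with two-tailed unpaired Student's t-tests (pooled variance).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from matplotlib.path import Path as MplPath
from scipy import stats

from .core import ZStack, as_image

__all__ = [
    "QuantROI",
    "VolumeTimeSeries",
    "PhaseStats",
    "sum_project",
    "integrate_roi",
    "normalize_series",
    "phase_stats",
    "TRANSIENT_WINDOW_MIN",
    "SUSTAINED_WINDOW_MIN",
]

TRANSIENT_WINDOW_MIN = (1.0, 3.0)
SUSTAINED_WINDOW_MIN = (26.0, 30.0)

LABELS = ("stimulated", "adjacent", "dendrite", "background")


@dataclass(frozen=True)
class QuantROI:
    """An oval or polygonal quantification region.

    Oval: ``center=(row, col)``, ``semi_axes=(a_row, a_col)``.
    Polygon: ``vertices`` as (row, col) pairs. A pixel belongs to the
    ROI when its center falls inside the shape (deterministic and
    resolution-independent).
    """

    kind: str  # "oval" | "polygon"
    label: str  # "stimulated" | "adjacent" | "dendrite"
    center: tuple[float, float] | None = None
    semi_axes: tuple[float, float] | None = None
    vertices: tuple | None = None

    def __post_init__(self):
        if self.kind not in ("oval", "polygon"):
            raise ValueError("kind must be 'oval' or 'polygon'")
        if self.label not in LABELS:
            raise ValueError(f"label must be one of {LABELS}")
        if self.kind == "oval":
            if self.center is None or self.semi_axes is None:
                raise ValueError("oval ROI needs center and semi_axes")
            if min(self.semi_axes) <= 0:
                raise ValueError("oval semi-axes must be positive")
        else:
            if self.vertices is None or len(self.vertices) < 3:
                raise ValueError("polygon ROI needs >= 3 vertices")

    def mask(self, shape: tuple[int, int]) -> np.ndarray:
        """Boolean pixel-center containment mask for an image shape."""
        h, w = shape
        rr, cc = np.mgrid[0:h, 0:w]
        if self.kind == "oval":
            (r0, c0), (ar, ac) = self.center, self.semi_axes
            inside = ((rr - r0) / ar) ** 2 + ((cc - c0) / ac) ** 2 <= 1.0
        else:
            path = MplPath(np.asarray(self.vertices, dtype=float)[:, ::-1])
            pts = np.column_stack([cc.ravel(), rr.ravel()])
            inside = path.contains_points(pts).reshape(h, w)
        if not inside.any():
            raise ValueError("ROI covers no pixel centers")
        return inside

    def to_dict(self) -> dict:
        d = {"kind": self.kind, "label": self.label}
        if self.kind == "oval":
            d["center"] = list(self.center)
            d["semi_axes"] = list(self.semi_axes)
        else:
            d["vertices"] = [list(v) for v in self.vertices]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "QuantROI":
        kw = dict(kind=d["kind"], label=d["label"])
        if d["kind"] == "oval":
            kw["center"] = tuple(d["center"])
            kw["semi_axes"] = tuple(d["semi_axes"])
        else:
            kw["vertices"] = tuple(tuple(v) for v in d["vertices"])
        return cls(**kw)


def sum_project(stack: ZStack) -> np.ndarray:
    """Pixelwise sum of all slices of a stack (the 2D volume readout)."""
    if isinstance(stack, ZStack):
        return stack.slices.sum(axis=0)
    arr = np.asarray(stack, dtype=np.float64)
    if arr.ndim == 2:  # single-slice stack degenerates to the slice itself
        return arr.copy()
    if arr.ndim != 3 or arr.shape[0] < 1:
        raise ValueError("expected a non-empty stack")
    return arr.sum(axis=0)


def integrate_roi(image, roi: QuantROI,
                  background_roi: QuantROI | None = None) -> float:
    """Integrated intensity inside an ROI, optionally background-corrected.

    With ``background_roi`` given, the mean background intensity times
    the ROI pixel count is subtracted.
    """
    img = as_image(image)
    mask = roi.mask(img.shape)
    total = float(img[mask].sum())
    if background_roi is not None:
        bg = background_roi.mask(img.shape)
        total -= float(img[bg].mean()) * int(mask.sum())
    return total


@dataclass
class VolumeTimeSeries:
    """Normalized volume traces, one per object, on a shared time axis.

    ``times_min`` are minutes relative to uncaging onset (t = 0);
    ``values`` maps object id -> normalized trace; ``labels`` maps
    object id -> group label. By construction each object's
    pre-uncaging mean is 1.
    """

    times_min: np.ndarray
    values: dict[str, np.ndarray]
    labels: dict[str, str] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        """Tidy frame with both V/V0 and the change (V-V0)/V0 columns."""
        rows = []
        for obj, trace in self.values.items():
            label = self.labels.get(obj, "")
            for t, v in zip(self.times_min, trace):
                rows.append((float(t), obj, label, float(v), float(v) - 1.0))
        return pd.DataFrame(
            rows,
            columns=["time_min", "object_id", "label",
                     "normalized_volume", "volume_change"],
        )

    def window_means(self, window: tuple[float, float]) -> dict[str, float]:
        """Per-object mean normalized volume over a closed time window."""
        lo, hi = window
        sel = (self.times_min >= lo) & (self.times_min <= hi)
        if not sel.any():
            raise ValueError(f"no samples in window [{lo}, {hi}] min")
        return {obj: float(trace[sel].mean())
                for obj, trace in self.values.items()}


def normalize_series(times_min, raw_traces: dict[str, Sequence[float]],
                     labels: dict[str, str] | None = None,
                     pre_window: tuple[float, float] | None = None
                     ) -> VolumeTimeSeries:
    """Standardize each object's trace to its average pre-uncaging value.

    ``pre_window`` defaults to all times < 0. Idempotent on already
    normalized traces. Fails on a non-positive pre-window mean (an
    empty or dark baseline cannot anchor the normalization).
    """
    times = np.asarray(times_min, dtype=np.float64)
    if pre_window is None:
        pre = times < 0
    else:
        pre = (times >= pre_window[0]) & (times <= pre_window[1])
    if not pre.any():
        raise ValueError("no pre-uncaging time points to normalize against")
    values = {}
    for obj, trace in raw_traces.items():
        arr = np.asarray(trace, dtype=np.float64)
        if arr.shape != times.shape:
            raise ValueError(f"trace {obj!r} length mismatch with time axis")
        baseline = arr[pre].mean()
        if baseline <= 0:
            raise ValueError(f"non-positive pre-uncaging mean for {obj!r}")
        values[obj] = arr / baseline
    return VolumeTimeSeries(times_min=times, values=values,
                            labels=dict(labels or {}))


@dataclass(frozen=True)
class PhaseStats:
    """Window means and the t-test of one group against the dendrite control."""

    group: str
    window: tuple[float, float]
    group_mean_change: float
    control_mean_change: float
    t_statistic: float
    p_value: float
    n_group: int
    n_control: int


def _ttest(group_vals: np.ndarray, control_vals: np.ndarray):
    # Student's pooled-variance unpaired t-test, two-tailed
    t, p = stats.ttest_ind(group_vals, control_vals, equal_var=True)
    return float(t), float(p)


def phase_stats(series: VolumeTimeSeries,
                windows=(TRANSIENT_WINDOW_MIN, SUSTAINED_WINDOW_MIN),
                control_label: str = "dendrite") -> list[PhaseStats]:
    """Transient/sustained statistics of each group vs the dendrite control.

    For every non-control label present, computes the group's mean
    normalized change (V/V0 - 1) over each window and a two-tailed
    unpaired t-test of the per-object window means against the control
    group's. Requires >= 2 objects per group for the tests.
    """
    results = []
    by_label: dict[str, list[str]] = {}
    for obj, label in series.labels.items():
        by_label.setdefault(label, []).append(obj)
    if control_label not in by_label:
        raise ValueError(f"no objects labeled {control_label!r}")
    for window in windows:
        means = series.window_means(window)
        control = np.array([means[o] - 1.0 for o in by_label[control_label]])
        for label in sorted(by_label):
            if label == control_label:
                continue
            grp = np.array([means[o] - 1.0 for o in by_label[label]])
            if len(grp) < 2 or len(control) < 2:
                raise ValueError("need >= 2 objects per group for t-tests")
            t, p = _ttest(grp, control)
            results.append(PhaseStats(
                group=label, window=tuple(window),
                group_mean_change=float(grp.mean()),
                control_mean_change=float(control.mean()),
                t_statistic=t, p_value=p,
                n_group=len(grp), n_control=len(control),
            ))
    return results


def stats_to_frame(results: Sequence[PhaseStats]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (
                r.group, r.window[0], r.window[1], r.group_mean_change,
                r.control_mean_change, r.t_statistic, r.p_value,
                r.n_group, r.n_control,
            )
            for r in results
        ],
        columns=[
            "group", "window_start_min", "window_end_min",
            "group_mean_change", "control_mean_change",
            "t_statistic", "p_value", "n_group", "n_control",
        ],
    )
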