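"""Autofocus over Z-stacks and the operator-selection benchmark.

Best focus is the slice maximizing a focus measure; the benchmark
scores each operator on annotated stacks with a *relative accuracy*
metric standardized per stack: 100% when the selected slice coincides
with the annotated target, 0% at the maximum possible distance from it,
and 50% in expectation for a position drawn uniformly at random over
the continuous Z range when the target sits at the stack center.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import RectROI, ZStack
from .focus_measures import compute_focus, get_operator, list_operators

__all__ = [
    "AutofocusConfig",
    "focus_curve",
    "best_focus",
    "relative_accuracy",
    "benchmark_operators",
]


@dataclass
class AutofocusConfig:
    """Parameters of one autofocus routine.

    ``range_um`` is the half-range searched around the current Z,
    ``step_um`` the slice spacing, and ``frequency`` means the routine
    runs every k-th imaging cycle. ``correction_mode`` selects whether
    the compensating move is a galvanometer scan shift or a motor
    repositioning (identical math; logged differently).
    """

    range_um: float = 1.5
    step_um: float = 0.5
    frequency: int = 1
    operator_id: str = "BREN"
    roi: RectROI | None = None
    correction_mode: str = "scan-shift"
    use_etl: bool = True

    def __post_init__(self):
        if self.range_um <= 0:
            raise ValueError("range_um must be positive")
        if self.step_um <= 0:
            raise ValueError("step_um must be positive")
        if self.frequency < 1:
            raise ValueError("frequency must be >= 1")
        if self.correction_mode not in ("scan-shift", "motor"):
            raise ValueError("correction_mode must be 'scan-shift' or 'motor'")
        get_operator(self.operator_id)  # fail fast on unknown ids

    @property
    def n_slices(self) -> int:
        return 2 * int(round(self.range_um / self.step_um)) + 1

    def z_offsets(self) -> np.ndarray:
        k = int(round(self.range_um / self.step_um))
        return np.arange(-k, k + 1) * self.step_um


def focus_curve(stack: ZStack, op, roi: RectROI | None = None,
                **params) -> list[tuple[float, float]]:
    """Focus value of every slice, in stack order, as (z, value) pairs."""
    return [
        (float(z), compute_focus(img, op, roi=roi, **params))
        for z, img in zip(stack.z_positions, stack.slices)
    ]


def _argmax_centerward(values: np.ndarray) -> int:
    """Index of the max; ties resolved toward the center, then lower index."""
    values = np.asarray(values, dtype=np.float64)
    best = np.flatnonzero(values == values.max())
    center = len(values) // 2  # center slice (upper middle for even stacks)
    # stable ordering: distance to center, then index
    return int(min(best, key=lambda i: (abs(i - center), i)))


def best_focus(stack: ZStack, op, roi: RectROI | None = None,
               **params) -> int:
    """Slice index with the maximal focus value.

    Ties are broken toward the stack center (the previous best-focus
    estimate in a tracking loop), then toward the lower index.
    """
    curve = focus_curve(stack, op, roi=roi, **params)
    return _argmax_centerward(np.array([v for _, v in curve]))


def relative_accuracy(z_selected: float, z_target: float,
                      n_slices: int) -> float:
    """Standardized distance score between selected and target Z, in %.

    100 means the selection coincides with the target, 0 means the
    selection is at the maximum possible distance from the target
    within the stack. Positions may be fractional (a continuous Z over
    the slice-index axis); the degenerate single-possible-position case
    scores 100.
    """
    if n_slices < 1:
        raise ValueError("n_slices must be >= 1")
    if not (0 <= z_selected <= n_slices - 1) or not (0 <= z_target <= n_slices - 1):
        raise ValueError("positions must lie within [0, n_slices-1]")
    d_max = max(z_target, (n_slices - 1) - z_target)
    if d_max == 0:
        return 100.0
    return 100.0 * (1.0 - abs(z_selected - z_target) / d_max)


@dataclass
class BenchmarkResult:
    """Per-operator mean relative accuracy (%) and mean per-slice time (s).

    Timings are informational only (they depend on the host); accuracy
    is deterministic given the dataset.
    """

    accuracy_pct: dict[str, float] = field(default_factory=dict)
    mean_time_s: dict[str, float] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "operator": list(self.accuracy_pct),
                "accuracy_pct": list(self.accuracy_pct.values()),
                "mean_time_s": [self.mean_time_s[k] for k in self.accuracy_pct],
            }
        )
        return df.sort_values(
            ["accuracy_pct", "operator"], ascending=[False, True]
        ).reset_index(drop=True)


def benchmark_operators(dataset, ops=None) -> BenchmarkResult:
    """Score focus operators against annotated Z-stacks.

    ``dataset`` is a sequence of ``(stack, target_index, roi)`` triples
    (roi may be None). ``ops`` defaults to every registered operator.
    Accuracy is standardized per stack and averaged arithmetically.
    """
    dataset = list(dataset)
    if not dataset:
        raise ValueError("benchmark dataset is empty")
    for stack, target, _roi in dataset:
        if not (0 <= target < stack.n_slices):
            raise ValueError(f"target index {target} outside stack")
    op_ids = sorted(ops) if ops is not None else sorted(list_operators())

    result = BenchmarkResult()
    for op_id in op_ids:
        accs = []
        total_time = 0.0
        total_slices = 0
        for stack, target, roi in dataset:
            t0 = time.perf_counter()
            picked = best_focus(stack, op_id, roi=roi)
            total_time += time.perf_counter() - t0
            total_slices += stack.n_slices
            accs.append(relative_accuracy(picked, target, stack.n_slices))
        result.accuracy_pct[op_id] = float(np.mean(accs))
        result.mean_time_s[op_id] = total_time / total_slices
    return result
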