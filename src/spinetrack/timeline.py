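"""Discrete-event timeline for interleaved multi-position imaging/uncaging.

Each imaging position owns timer steps: an imaging step fires once per
period for its whole duration, an uncaging step fires exactly once.
Every firing appends an action to a FIFO event queue. A separate
activation timer ticks every 0.1 s of session time; when the queue is
non-empty at a tick, the front action is executed and the activation
timer pauses until the action completes, so no two actions ever run
concurrently and positions can be added or deleted mid-session without
conflicts.

All semantics here run on a virtual clock so schedules are exactly
reproducible; a wall-clock driver with the same semantics is provided
for live use.
"""

from __future__ import annotations

import heapq
import math
import time as _time
from collections import deque
from dataclasses import dataclass
from typing import Callable, Iterable, Sequence

import pandas as pd

__all__ = [
    "TimelineStep",
    "SessionPlan",
    "ExecutionRecord",
    "fire_times",
    "rotate_positions",
    "run_queue",
    "run_queue_wallclock",
]

_TIME_DECIMALS = 9  # virtual-clock times are rounded to nanoseconds


def _t(x: float) -> float:
    return round(float(x), _TIME_DECIMALS)


@dataclass(frozen=True)
class TimelineStep:
    """One timer of a position's timeline.

    ``kind`` is ``"imaging"`` (fires every ``period_s`` from ``start_s``
    through ``start_s + duration_s``, inclusive) or ``"uncaging"``
    (fires exactly once at ``start_s``). Times are seconds relative to
    the position's admission into the session.
    """

    position_id: str
    kind: str
    start_s: float
    duration_s: float = 0.0
    period_s: float | None = None

    def __post_init__(self):
        if self.kind not in ("imaging", "uncaging"):
            raise ValueError("kind must be 'imaging' or 'uncaging'")
        if self.start_s < 0 or self.duration_s < 0:
            raise ValueError("start and duration must be non-negative")
        if self.kind == "imaging":
            if self.period_s is None or self.period_s <= 0:
                raise ValueError("imaging steps need a positive period_s")


def fire_times(step: TimelineStep) -> list[float]:
    """Times at which a step's timer fires.

    Imaging: ``start, start+period, ...`` while ``t <= start+duration``
    (inclusive end). Uncaging: the single time ``[start]``.
    """
    if step.kind == "uncaging":
        return [_t(step.start_s)]
    n = int(math.floor(step.duration_s / step.period_s + 1e-9))
    return [_t(step.start_s + k * step.period_s) for k in range(n + 1)]


@dataclass
class SessionPlan:
    """Declarative multi-position schedule.

    ``capacity`` caps how many positions are active concurrently
    (``None`` = unbounded); excess positions are rotated in as active
    ones finish. ``tick_s`` is the activation-timer period.
    """

    steps: list[TimelineStep]
    capacity: int | None = None
    tick_s: float = 0.1

    def __post_init__(self):
        if self.capacity is not None and self.capacity < 1:
            raise ValueError("capacity must be >= 1")
        if self.tick_s <= 0:
            raise ValueError("tick_s must be positive")

    def position_ids(self) -> list[str]:
        """Positions in definition order (first step occurrence)."""
        seen: dict[str, None] = {}
        for s in self.steps:
            seen.setdefault(s.position_id, None)
        return list(seen)

    def steps_for(self, position_id: str) -> list[TimelineStep]:
        return [s for s in self.steps if s.position_id == position_id]

    def to_dict(self) -> dict:
        return {
            "capacity": self.capacity,
            "tick_s": self.tick_s,
            "steps": [
                {
                    "position_id": s.position_id,
                    "kind": s.kind,
                    "start_s": s.start_s,
                    "duration_s": s.duration_s,
                    "period_s": s.period_s,
                }
                for s in self.steps
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SessionPlan":
        steps = [TimelineStep(**s) for s in d["steps"]]
        return cls(steps=steps, capacity=d.get("capacity"),
                   tick_s=d.get("tick_s", 0.1))


@dataclass(frozen=True)
class ExecutionRecord:
    """One executed action: when it was enqueued, ran, and for whom."""

    enqueue_t: float
    start_t: float
    end_t: float
    position_id: str
    action: str


def log_to_frame(log: Sequence[ExecutionRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (r.enqueue_t, r.start_t, r.end_t, r.position_id, r.action)
            for r in log
        ],
        columns=["enqueue_t", "start_t", "end_t", "position_id", "action"],
    )


def rotate_positions(plan: SessionPlan, capacity: int | None = None,
                     deleted: Iterable[str] = ()) -> dict[str, float]:
    """Admission time of each position under a concurrency cap.

    The first ``capacity`` positions (definition order) start at t=0; a
    waiting position is admitted one activation tick after the earliest
    active position's final timer firing. Positions named in ``deleted``
    are dropped before admission and never appear in any log.
    """
    cap = capacity if capacity is not None else plan.capacity
    deleted = set(deleted)
    order = [p for p in plan.position_ids() if p not in deleted]
    if cap is None:
        cap = max(len(order), 1)
    if cap < 1:
        raise ValueError("capacity must be >= 1")

    admissions: dict[str, float] = {}
    active: list[float] = []  # finish times of occupied slots
    for pos in order:
        steps = plan.steps_for(pos)
        span = max(fire_times(s)[-1] for s in steps) if steps else 0.0
        if len(active) < cap:
            t_admit = 0.0
        else:
            t_admit = _t(heapq.heappop(active) + plan.tick_s)
        admissions[pos] = t_admit
        heapq.heappush(active, _t(t_admit + span))
    return admissions


def _collect_firings(plan: SessionPlan, admissions: dict[str, float]):
    """(fire_time, definition_index, position, action) sorted for FIFO."""
    order = {p: i for i, p in enumerate(plan.position_ids())}
    fires = []
    for idx, step in enumerate(plan.steps):
        base = admissions.get(step.position_id)
        if base is None:
            continue
        for t in fire_times(step):
            fires.append((_t(base + t), order[step.position_id], idx,
                          step.position_id, step.kind))
    fires.sort()
    return fires


def run_queue(plan: SessionPlan,
              executor: Callable[[str, str], float],
              deleted: Iterable[str] = ()) -> list[ExecutionRecord]:
    """Execute a plan on the virtual clock; returns the execution log.

    ``executor(position_id, action)`` performs the action and returns
    its completion duration in seconds (deterministic executors give
    bit-identical logs across repeats); an executor accepting a third
    parameter also receives the virtual start time. Actions are
    dequeued strictly FIFO at activation ticks; the activation timer is
    paused while an action runs, so execution intervals never overlap.
    A long action delays — never drops — pending firings.
    """
    import inspect

    try:
        n_params = len(inspect.signature(executor).parameters)
    except (TypeError, ValueError):
        n_params = 2
    admissions = rotate_positions(plan, deleted=deleted)
    fires = _collect_firings(plan, admissions)
    tick = plan.tick_s

    log: list[ExecutionRecord] = []
    queue: deque = deque()
    i = 0
    now = _t(tick)  # first activation tick
    while i < len(fires) or queue:
        while i < len(fires) and fires[i][0] <= now + 1e-9:
            ft, _order, _idx, pos, action = fires[i]
            queue.append((ft, pos, action))
            i += 1
        if queue:
            enq_t, pos, action = queue.popleft()
            if n_params >= 3:
                duration = float(executor(pos, action, now))
            else:
                duration = float(executor(pos, action))
            if not (duration >= 0 and math.isfinite(duration)):
                raise ValueError("executor must return a finite duration >= 0")
            end = _t(now + duration)
            log.append(ExecutionRecord(enq_t, now, end, pos, action))
            now = _t(end + tick)  # timer resumes after completion
        elif i < len(fires):
            # idle ticks: jump to the first tick at/after the next firing
            gap = fires[i][0] - now
            k = max(int(math.ceil(gap / tick - 1e-9)), 1)
            now = _t(now + k * tick)
        else:
            break
    return log


def run_queue_wallclock(plan: SessionPlan,
                        executor: Callable[[str, str], float],
                        deleted: Iterable[str] = (),
                        sleep=_time.sleep,
                        clock=_time.monotonic) -> list[ExecutionRecord]:
    """Wall-clock driver with the same queue semantics as :func:`run_queue`.

    Ticks are realized by sleeping; executor duration is measured, not
    declared. Intended for live sessions, not for tests.
    """
    admissions = rotate_positions(plan, deleted=deleted)
    fires = _collect_firings(plan, admissions)
    tick = plan.tick_s

    log: list[ExecutionRecord] = []
    queue: deque = deque()
    i = 0
    t0 = clock()
    while i < len(fires) or queue:
        sleep(tick)
        now = clock() - t0
        while i < len(fires) and fires[i][0] <= now:
            ft, _order, _idx, pos, action = fires[i]
            queue.append((ft, pos, action))
            i += 1
        if queue:
            enq_t, pos, action = queue.popleft()
            start = clock() - t0
            executor(pos, action)
            end = clock() - t0
            log.append(ExecutionRecord(enq_t, start, end, pos, action))
    return log
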