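"""Event-queue scheduler: firing rules, FIFO execution, rotation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as hst

from spinetrack.timeline import (SessionPlan, TimelineStep, fire_times,
                                 log_to_frame, rotate_positions, run_queue)


def test_fire_times_examples():
    imaging = TimelineStep("A", "imaging", start_s=0, duration_s=300,
                           period_s=60)
    assert fire_times(imaging) == [0, 60, 120, 180, 240, 300]
    assert fire_times(TimelineStep("A", "uncaging", start_s=600)) == [600]
    single = TimelineStep("A", "imaging", start_s=5, duration_s=0, period_s=60)
    assert fire_times(single) == [5]


def test_step_validation():
    with pytest.raises(ValueError):
        TimelineStep("A", "imaging", start_s=0, duration_s=10)  # no period
    with pytest.raises(ValueError):
        TimelineStep("A", "blinking", start_s=0)
    with pytest.raises(ValueError):
        TimelineStep("A", "uncaging", start_s=-1)


def test_run_queue_tick_and_pause_semantics():
    # two actions enqueued at t=0, each taking 1 s: the first activates
    # at the first 0.1 s tick; the timer pauses during execution and the
    # second starts one tick after the first completes
    plan = SessionPlan(steps=[TimelineStep("A", "uncaging", 0),
                              TimelineStep("B", "uncaging", 0)])
    log = run_queue(plan, lambda p, a: 1.0)
    assert [(r.start_t, r.end_t, r.position_id) for r in log] == [
        (0.1, 1.1, "A"), (1.2, 2.2, "B")
    ]
    assert all(r.enqueue_t == 0.0 for r in log)


def test_empty_plan_gives_empty_log():
    assert run_queue(SessionPlan(steps=[]), lambda p, a: 1.0) == []


def test_staggered_uncaging_has_zero_queue_wait():
    steps = []
    for i in range(4):
        steps.append(TimelineStep(f"P{i}", "imaging", start_s=0,
                                  duration_s=120, period_s=60))
        steps.append(TimelineStep(f"P{i}", "uncaging", start_s=130 + 30 * i))
    log = run_queue(SessionPlan(steps=steps), lambda p, a: 2.0)
    uncagings = [r for r in log if r.action == "uncaging"]
    assert len(uncagings) == 4
    for r in uncagings:
        assert r.start_t - r.enqueue_t <= 0.1 + 1e-9  # picked up next tick


def test_rotation_admissions():
    steps = [TimelineStep(f"P{i}", "imaging", 0, 600, 60) for i in range(5)]
    plan = SessionPlan(steps=steps)
    assert rotate_positions(plan, capacity=3) == pytest.approx(
        {"P0": 0.0, "P1": 0.0, "P2": 0.0, "P3": 600.1, "P4": 600.1}
    )
    seq = rotate_positions(plan, capacity=1)
    assert list(seq) == [f"P{i}" for i in range(5)]
    assert [seq[p] for p in seq] == pytest.approx(
        [0.0, 600.1, 1200.2, 1800.3, 2400.4]
    )


def test_deleted_waiting_position_never_runs():
    steps = [TimelineStep(f"P{i}", "imaging", 0, 10, 5) for i in range(3)]
    plan = SessionPlan(steps=steps, capacity=1)
    log = run_queue(plan, lambda p, a: 0.5, deleted={"P1"})
    assert {r.position_id for r in log} == {"P0", "P2"}


def test_long_action_delays_but_never_drops_firings():
    plan = SessionPlan(steps=[
        TimelineStep("A", "imaging", 0, 120, 30),  # fires 0,30,60,90,120
    ])
    log = run_queue(plan, lambda p, a: 45.0)  # each action outlasts the period
    assert len(log) == 5
    assert [r.enqueue_t for r in log] == [0, 30, 60, 90, 120]


plan_strategy = hst.lists(
    hst.tuples(
        hst.integers(0, 3),                      # position index
        hst.sampled_from(["imaging", "uncaging"]),
        hst.integers(0, 50),                     # start (x10 s)
        hst.integers(0, 6),                      # duration (x10 s)
        hst.integers(1, 4),                      # period (x10 s)
    ),
    min_size=1, max_size=8,
)


@given(raw=plan_strategy, dur_seed=hst.integers(0, 2**16))
@settings(max_examples=60, deadline=None)
def test_queue_invariants_hold_on_random_plans(raw, dur_seed):
    steps = [
        TimelineStep(f"P{p}", kind, start_s=10.0 * s, duration_s=10.0 * d,
                     period_s=10.0 * per if kind == "imaging" else None)
        for p, kind, s, d, per in raw
    ]
    plan = SessionPlan(steps=steps)
    durations = np.random.default_rng(dur_seed).uniform(0.0, 12.0, size=4096)
    counter = [0]

    def executor(pos, action):
        counter[0] += 1
        return float(durations[counter[0] % len(durations)])

    log = run_queue(plan, executor)
    # every firing executed exactly once
    n_fires = sum(len(fire_times(s)) for s in steps)
    assert len(log) == n_fires
    # mutual exclusion and FIFO
    for a, b in zip(log, log[1:]):
        assert b.start_t >= a.end_t - 1e-9
        assert (a.enqueue_t, ) <= (b.enqueue_t, )
    # uncaging steps fire exactly once per step
    n_uncage = sum(1 for s in steps if s.kind == "uncaging")
    assert sum(1 for r in log if r.action == "uncaging") == n_uncage
    # determinism: bit-identical on repeat
    counter[0] = 0
    log2 = run_queue(plan, executor)
    assert log2 == log


def test_plan_round_trip_and_frame():
    plan = SessionPlan(steps=[
        TimelineStep("A", "imaging", 0, 60, 20),
        TimelineStep("B", "uncaging", 30),
    ], capacity=2)
    clone = SessionPlan.from_dict(plan.to_dict())
    assert clone.to_dict() == plan.to_dict()
    df = log_to_frame(run_queue(plan, lambda p, a: 0.2))
    assert list(df.columns) == ["enqueue_t", "start_t", "end_t",
                                "position_id", "action"]
    assert len(df) == 5
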