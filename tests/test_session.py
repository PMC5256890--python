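"""Closed-loop session runner: mapping, tracking, uncaging, spine loss."""

import numpy as np
import pytest

from spinetrack.session import (SessionConfig, VirtualPosition, motor_to_scan,
                                run_session, run_tracking_trial, scan_to_motor)
from spinetrack.synthetic import (DriftModel, Phantom, PlasticityModel)
from spinetrack.timeline import SessionPlan, TimelineStep


def test_motor_to_scan_linear_and_invertible(rng):
    center = (100.0, -50.0)
    assert motor_to_scan(center, center, fov_size_um=200.0) == (0.0, 0.0)
    for _ in range(20):
        pos = tuple(np.array(center) + rng.uniform(-99, 99, size=2))
        off = motor_to_scan(pos, center, 200.0)
        back = scan_to_motor(off, center, 200.0)
        assert back == pytest.approx(pos, abs=1e-9)
    with pytest.raises(ValueError):
        motor_to_scan((center[0] + 150.0, center[1]), center, 200.0)


def _plan(duration_s=300.0, period_s=60.0, uncage_at=120.0):
    steps = [TimelineStep("P0", "imaging", 0.0, duration_s, period_s)]
    if uncage_at is not None:
        steps.append(TimelineStep("P0", "uncaging", uncage_at))
    return SessionPlan(steps=steps)


def test_null_session_tracks_perfectly():
    """No drift, no noise: zero shift estimates, constant focus, flat
    pre-uncaging volume traces."""
    config = SessionConfig(snr=None)
    result = run_session(_plan(), [VirtualPosition("P0")], config=config,
                         seed=0)
    img = result.log[result.log["action"] == "imaging"]
    assert len(img) == 6
    assert (img["d_row_px"] == 0).all() and (img["d_col_px"] == 0).all()
    assert img["focus_index"].nunique() == 1
    assert (img["tracking_error_px"] == 0).all()
    series = result.series
    pre = series.times_min < 0
    for obj, trace in series.values.items():
        assert np.allclose(trace[pre], 1.0)


def test_plasticity_raises_only_the_stimulated_trace():
    config = SessionConfig(snr=None)
    pos = VirtualPosition("P0", plasticity=PlasticityModel(
        a_trans=2.0, tau_trans_min=1.5, a_sust=0.6))
    result = run_session(_plan(duration_s=600.0, uncage_at=120.0), [pos],
                         config=config, seed=0)
    series = result.series
    post = series.times_min > 1.0
    stim = [v for o, v in series.values.items()
            if series.labels[o] == "stimulated"][0]
    dend = [v for o, v in series.values.items()
            if series.labels[o] == "dendrite"][0]
    assert stim[post].mean() > 1.5
    assert dend[post].mean() == pytest.approx(1.0, abs=0.02)


def test_uncaging_event_logged_with_depth_params():
    pos = VirtualPosition("P0", z_depth_um=25.0)
    config = SessionConfig(snr=None, depth_min_um=0.0, depth_max_um=50.0)
    result = run_session(_plan(), [pos], config=config, seed=0)
    unc = result.log[result.log["action"] == "uncaging"]
    assert len(unc) == 1
    assert unc["pulse_ms"].iloc[0] == pytest.approx(6.0)
    assert unc["power_mW"].iloc[0] == pytest.approx(3.75)
    # relocated target sits on bright structure
    r, c = int(unc["target_row"].iloc[0]), int(unc["target_col"].iloc[0])
    assert 0 <= r < 128 and 0 <= c < 128


def test_staggered_multi_position_uncaging_never_overlaps():
    steps = []
    for i in range(5):
        steps.append(TimelineStep(f"P{i}", "imaging", 0.0, 240.0, 60.0))
        steps.append(TimelineStep(f"P{i}", "uncaging", 250.0 + 40.0 * i))
    plan = SessionPlan(steps=steps)
    positions = [VirtualPosition(f"P{i}") for i in range(5)]
    config = SessionConfig(snr=None, uncaging_action_s=30.0)
    result = run_session(plan, positions, config=config, seed=0)
    unc = result.log[result.log["action"] == "uncaging"]
    assert len(unc) == 5
    assert unc["position_id"].nunique() == 5
    starts = np.sort(unc["time_s"].to_numpy())
    assert (np.diff(starts) >= 30.0).all()  # mutual exclusion


def test_dark_position_is_declared_lost_after_three_failures():
    dark = Phantom(dendrite_intensity=0.0, spines=())
    steps = [TimelineStep("P0", "uncaging", float(t)) for t in (10, 20, 30, 40)]
    pos = VirtualPosition("P0", phantom=dark,
                          uncaging_target=None)
    from spinetrack.uncaging import TargetPoint

    pos.uncaging_target = TargetPoint(64, 64)
    config = SessionConfig(snr=None, max_relocation_failures=3)
    result = run_session(SessionPlan(steps=steps), [pos], config=config,
                         seed=0)
    assert result.lost_positions == ["P0"]
    failed = result.log[result.log["action"] == "uncaging-failed"]
    assert len(failed) == 3  # the 4th event is skipped, not attempted
    skipped = result.log[result.log["action"].str.endswith("skipped-lost")]
    assert len(skipped) == 1


def test_closed_loop_tracks_random_walk_drift():
    out = run_tracking_trial(seed=11, duration_min=20.0,
                             drift_sigma_um=0.15)
    assert out["n_frames"] == 21
    assert out["final_error_px"] <= 2.0
    assert out["final_focal_error_um"] <= 0.5 + 1e-9


def test_uncorrected_drift_grows_like_the_random_walk():
    """With correction the error stays bounded; the raw drift does not."""
    plan = _plan(duration_s=1800.0, period_s=60.0, uncage_at=None)
    config = SessionConfig(drift=DriftModel(sigma_um=(0.15, 0.15, 0.0)),
                           snr=None)
    result = run_session(plan, [VirtualPosition("P0")], config=config, seed=3)
    img = result.log[result.log["action"] == "imaging"]
    # ground-truth drift accumulated far beyond the residual error
    raw_drift_px = np.hypot(img["d_row_px"].cumsum(), img["d_col_px"].cumsum())
    assert raw_drift_px.iloc[-1] > 2.0 * img["tracking_error_px"].iloc[-1]
    assert img["tracking_error_px"].max() <= 3.0
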