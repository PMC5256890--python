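"""Closed-loop virtual imaging sessions.

Maps motor positions into a shared field of view, runs the timeline
scheduler, and for every imaging event acquires a Z-stack from the
virtual microscope, refocuses (updating the Z estimate), estimates
lateral drift against the position's reference image and applies the
compensating scan shift, then quantifies the configured ROIs. Every
uncaging event relocates the stored target onto the spine perimeter
and logs depth-modulated stimulus parameters. Ground-truth tracking
error is recorded per frame, which is how the tracking guarantees are
validated.

Reference images are captured once at position definition and never
updated during a session (re-baselining would let the reference itself
drift); an optional flag re-captures them after each correction. When
the zoomed-in drift estimate hits the half-frame aliasing bound of the
circular correlation, the runner falls back once to the zoomed-out
reference, whose wider field resolves larger displacements at coarser
resolution. A position is dropped from the rotation ("spine lost")
after three consecutive target-relocation failures.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .autofocus import AutofocusConfig, best_focus
from .drift import corrective_shift, estimate_shift
from .quantify import (QuantROI, VolumeTimeSeries, integrate_roi,
                       normalize_series, sum_project)
from .synthetic import (DriftModel, DriftState, Microscope, Phantom,
                        PlasticityModel, default_phantom, render_slice,
                        shot_noise_for_snr, spine_volume_factor, step_drift)
from .timeline import SessionPlan, TimelineStep, run_queue
from .uncaging import (SpineLostError, TargetPoint, relocate_target,
                       uncaging_params_for_depth)

__all__ = [
    "VirtualPosition",
    "SessionConfig",
    "SessionResult",
    "motor_to_scan",
    "scan_to_motor",
    "default_rois",
    "run_session",
    "run_tracking_trial",
    "simulate_plasticity_cohort",
]


# ---------------------------------------------------------------------------
# position mapping

def motor_to_scan(position_xy_um, fov_center_xy_um, fov_size_um: float,
                  scan_range: float = 2.0) -> tuple[float, float]:
    """Map a motor coordinate to a galvanometer scan offset.

    All positions inside one field of view are addressed purely by scan
    offsets relative to the single motor coordinate at the FOV center.
    The map is linear and invertible: the FOV edge (half ``fov_size_um``
    from center) corresponds to half ``scan_range`` in scan units.
    """
    d = np.asarray(position_xy_um, dtype=float) - np.asarray(
        fov_center_xy_um, dtype=float
    )
    if np.any(np.abs(d) > fov_size_um / 2.0):
        raise ValueError(
            f"position {tuple(position_xy_um)} outside the {fov_size_um} um FOV"
        )
    off = d / (fov_size_um / 2.0) * (scan_range / 2.0)
    return float(off[0]), float(off[1])


def scan_to_motor(scan_offset, fov_center_xy_um, fov_size_um: float,
                  scan_range: float = 2.0) -> tuple[float, float]:
    """Inverse of :func:`motor_to_scan`."""
    off = np.asarray(scan_offset, dtype=float)
    d = off / (scan_range / 2.0) * (fov_size_um / 2.0)
    pos = np.asarray(fov_center_xy_um, dtype=float) + d
    return float(pos[0]), float(pos[1])


# ---------------------------------------------------------------------------
# session configuration

@dataclass
class VirtualPosition:
    """One imaged position of the virtual specimen.

    Spine 0 of the phantom is the stimulated spine; ``plasticity``
    (when set) drives its volume after this position's uncaging event.
    ``z_depth_um`` is the position's depth in tissue, which modulates
    the uncaging pulse parameters.
    """

    position_id: str
    phantom: Phantom | None = None
    motor_xyz_um: tuple[float, float, float] = (0.0, 0.0, 0.0)
    z_depth_um: float = 20.0
    plasticity: PlasticityModel | None = None
    uncaging_target: TargetPoint | None = None
    notes: str = ""


@dataclass
class SessionConfig:
    """Everything the closed loop needs besides the plan and positions."""

    autofocus: AutofocusConfig = field(default_factory=AutofocusConfig)
    drift: DriftModel = field(default_factory=DriftModel)
    snr: float | None = 20.0  # None = noise-free
    background: float | str = "auto"
    uncaging_threshold_frac: float = 0.4
    depth_min_um: float = 0.0
    depth_max_um: float = 50.0
    imaging_action_s: float = 1.0
    uncaging_action_s: float = 30.0
    max_relocation_failures: int = 3
    rebaseline_references: bool = False


@dataclass
class SessionResult:
    """Execution log plus the normalized volume traces of a session."""

    log: pd.DataFrame
    series: VolumeTimeSeries | None
    lost_positions: list[str]


def default_rois(phantom: Phantom, scope: Microscope) -> list[QuantROI]:
    """Quantification ROIs matching the default phantom layout.

    Ovals over the stimulated (spine 0) and adjacent (spine 1) heads,
    sized to hold the fully enlarged, defocus-blurred head, a polygonal
    strip over a spine-free stretch of dendrite as control, and a
    structure-free background oval whose mean is subtracted from every
    other ROI's integral.
    """
    px = scope.pixel_um
    rois = []
    labels = ["stimulated", "adjacent"]
    semi_px = 1.2 / px
    for i, s in enumerate(phantom.spines[:2]):
        row_um, col_um = phantom.spine_head_center_um(i)
        rois.append(QuantROI(
            kind="oval", label=labels[i],
            center=(row_um / px, col_um / px),
            semi_axes=(semi_px, semi_px),
        ))
    band = (phantom.dendrite_radius_um + 0.4) / px
    row0 = phantom.dendrite_row_um / px
    anchors = sorted(s.anchor_um / px for s in phantom.spines) or [0.0]
    margin = 0.8 / px
    c0, c1 = 4.0, max(anchors[0] - margin, 12.0)
    rois.append(QuantROI(
        kind="polygon", label="dendrite",
        vertices=((row0 - band, c0), (row0 - band, c1),
                  (row0 + band, c1), (row0 + band, c0)),
    ))
    # structure-free corner, well clear of the dendrite band and spines
    rois.append(QuantROI(
        kind="oval", label="background",
        center=(1.4 / px, 1.4 / px), semi_axes=(1.0 / px, 1.0 / px),
    ))
    return rois


def split_background(rois: list[QuantROI]):
    """Separate the background ROI (if any) from the quantified ones."""
    quant = [r for r in rois if r.label != "background"]
    bg = next((r for r in rois if r.label == "background"), None)
    return quant, bg


# ---------------------------------------------------------------------------
# the closed loop

class _PositionState:
    """Mutable per-position tracking state during a session."""

    def __init__(self, pos: VirtualPosition, scope: Microscope,
                 config: SessionConfig, rng: np.random.Generator):
        self.pos = pos
        self.phantom = pos.phantom or default_phantom(scope)
        self.rng = rng
        self.noise = (
            shot_noise_for_snr(self.phantom, scope, config.snr,
                               background=config.background)
            if config.snr is not None else None
        )
        self.drift = DriftState()
        self.correction_px = np.zeros(2, dtype=int)  # applied scan shift
        self.z_est = self.phantom.z_focus_um
        self.relocation_failures = 0
        self.lost = False
        self.uncage_time_s: float | None = None
        self.last_t_s = 0.0
        # references captured at definition time (zero drift)
        self.scope = scope
        self.scope_out = replace(scope, pixel_um=scope.pixel_um * 2)
        self.ref_in = render_slice(self.phantom, scope, self.z_est,
                                   noise=self.noise, rng=rng)
        self.ref_out = render_slice(self.phantom, self.scope_out, self.z_est,
                                    noise=self.noise, rng=rng)
        if pos.uncaging_target is None and self.phantom.spines:
            r_um, c_um = self.phantom.spine_head_center_um(0)
            self.target = TargetPoint(int(r_um / scope.pixel_um),
                                      int(c_um / scope.pixel_um))
        else:
            self.target = pos.uncaging_target
        self.rois, self.bg_roi = split_background(
            default_rois(self.phantom, scope)
        )

    def volume_factors(self, t_s: float) -> np.ndarray:
        vf = np.ones(len(self.phantom.spines))
        if self.pos.plasticity is not None and self.uncage_time_s is not None:
            t_min = (t_s - self.uncage_time_s) / 60.0
            vf[0] = spine_volume_factor(self.pos.plasticity, t_min)
        return vf

    def residual_offset_um(self) -> tuple[float, float, float]:
        dr, dc, dz = self.drift.offset_um
        px = self.scope.pixel_um
        return (dr - self.correction_px[0] * px,
                dc - self.correction_px[1] * px, dz)


def run_session(plan: SessionPlan, positions: list[VirtualPosition],
                config: SessionConfig | None = None,
                scope: Microscope | None = None,
                seed: int = 0) -> SessionResult:
    """Run a full simulated session and return its log and volume traces.

    Scheduling follows the event-queue semantics of
    :mod:`spinetrack.timeline`; each action works against the virtual
    microscope with the session's drift and noise models, all seeded
    from ``seed``.
    """
    config = config or SessionConfig()
    scope = scope or Microscope()
    rng = np.random.default_rng(seed)
    af = config.autofocus
    states = {p.position_id: _PositionState(p, scope, config, rng)
              for p in positions}
    # uncaging onset per position, from the plan (admission-relative
    # starts; the scheduler may delay execution, onset uses plan time)
    for step in plan.steps:
        if step.kind == "uncaging" and step.position_id in states:
            states[step.position_id].uncage_time_s = step.start_s

    rows: list[dict] = []
    half_row = scope.frame_px // 2

    def executor(position_id: str, action: str, t_now: float) -> float:
        st = states[position_id]
        if st.lost:
            rows.append({"time_s": t_now, "position_id": position_id,
                         "action": f"{action}-skipped-lost"})
            return 0.0
        if action == "imaging":
            _do_imaging(st, t_now)
            return config.imaging_action_s
        _do_uncaging(st, t_now)
        return config.uncaging_action_s

    def _do_imaging(st: _PositionState, t_now: float):
        # one random-walk step per frame; creep follows elapsed time
        dt_min = (t_now - st.last_t_s) / 60.0
        st.last_t_s = t_now
        st.drift = step_drift(st.drift, config.drift, rng=st.rng,
                              dt_min=dt_min)
        vf = st.volume_factors(t_now)
        dr, dc, dz = st.residual_offset_um()
        k = int(round(af.range_um / af.step_um))
        z_positions = st.z_est + np.arange(-k, k + 1) * af.step_um
        slices = np.stack([
            render_slice(st.phantom, scope, z, lateral_offset_um=(dr, dc),
                         z_offset_um=dz, volume_factors=vf,
                         noise=st.noise, rng=st.rng)
            for z in z_positions
        ])
        from .core import ZStack

        stack = ZStack(slices=slices, z_positions=z_positions)
        idx = best_focus(stack, af.operator_id, roi=af.roi)
        st.z_est = float(stack.z_positions[idx])
        frame = stack.slices[idx]
        est = estimate_shift(st.ref_in, frame)
        fallback = abs(est.d_row) >= half_row or abs(est.d_col) >= half_row
        if fallback:
            # re-align once against the wider, coarser reference
            frame_out = render_slice(st.phantom, st.scope_out, st.z_est,
                                     lateral_offset_um=(dr, dc), z_offset_um=dz,
                                     volume_factors=vf, noise=st.noise,
                                     rng=st.rng)
            est_out = estimate_shift(st.ref_out, frame_out)
            st.correction_px += np.array([est_out.d_row, est_out.d_col]) * 2
        else:
            st.correction_px += np.array([est.d_row, est.d_col])
        if config.rebaseline_references:
            st.ref_in = render_slice(st.phantom, scope, st.z_est,
                                     noise=st.noise, rng=st.rng)
        proj = sum_project(stack)
        quant = {
            f"raw_{r.label}": integrate_roi(proj, r, background_roi=st.bg_roi)
            for r in st.rois
        }
        true_dr, true_dc, true_dz = st.drift.offset_um
        err = np.hypot(true_dr / scope.pixel_um - st.correction_px[0],
                       true_dc / scope.pixel_um - st.correction_px[1])
        rows.append({
            "time_s": t_now, "position_id": st.pos.position_id,
            "action": "imaging", "focus_index": idx, "z_est_um": st.z_est,
            "d_row_px": est.d_row, "d_col_px": est.d_col,
            "corrective_row_px": corrective_shift(est)[0],
            "corrective_col_px": corrective_shift(est)[1],
            "fallback_zoomed_out": fallback,
            "tracking_error_px": float(err),
            "focal_error_um": abs(st.z_est - (st.phantom.z_focus_um + true_dz)),
            "notes": st.pos.notes,
            **quant,
        })

    def _do_uncaging(st: _PositionState, t_now: float):
        vf = st.volume_factors(t_now)
        dr, dc, dz = st.residual_offset_um()
        frame = render_slice(st.phantom, scope, st.z_est,
                             lateral_offset_um=(dr, dc), z_offset_um=dz,
                             volume_factors=vf, noise=st.noise, rng=st.rng)
        params = uncaging_params_for_depth(
            st.pos.z_depth_um, config.depth_min_um, config.depth_max_um
        )
        try:
            new_target = relocate_target(
                frame, config.uncaging_threshold_frac, st.target, relative=True
            )
            st.relocation_failures = 0
        except SpineLostError:
            st.relocation_failures += 1
            if st.relocation_failures >= config.max_relocation_failures:
                st.lost = True
            rows.append({
                "time_s": t_now, "position_id": st.pos.position_id,
                "action": "uncaging-failed",
                "relocation_failures": st.relocation_failures,
                "lost": st.lost,
            })
            return
        rows.append({
            "time_s": t_now, "position_id": st.pos.position_id,
            "action": "uncaging",
            "target_row": new_target.row, "target_col": new_target.col,
            "pulse_ms": params.pulse_ms, "power_mW": params.power_mW,
            "n_pulses": params.n_pulses, "rate_Hz": params.rate_Hz,
        })

    run_queue(plan, executor)
    log = pd.DataFrame(rows)
    series = _build_series(log, states) if len(log) else None
    lost = [pid for pid, st in states.items() if st.lost]
    return SessionResult(log=log, series=series, lost_positions=lost)


def _build_series(log: pd.DataFrame, states) -> VolumeTimeSeries | None:
    """Normalized per-object volume traces from the imaging log."""
    img = log[log["action"] == "imaging"]
    if img.empty:
        return None
    raw_cols = [c for c in img.columns if c.startswith("raw_")]
    all_series: list[VolumeTimeSeries] = []
    for pid, grp in img.groupby("position_id", sort=False):
        st = states[pid]
        t0 = st.uncage_time_s if st.uncage_time_s is not None else 0.0
        times_min = (grp["time_s"].to_numpy() - t0) / 60.0
        traces, labels = {}, {}
        for col in raw_cols:
            if grp[col].isna().any():
                continue
            label = col[len("raw_"):]
            obj = f"{pid}/{label}"
            traces[obj] = grp[col].to_numpy()
            labels[obj] = label
        pre = None if (times_min < 0).any() else (times_min.min(), times_min.max())
        all_series.append(
            normalize_series(times_min, traces, labels, pre_window=pre)
        )
    if len(all_series) == 1:
        return all_series[0]
    # merge positions sharing a common time axis; otherwise keep the first
    base = all_series[0]
    for other in all_series[1:]:
        if (other.times_min.shape == base.times_min.shape
                and np.allclose(other.times_min, base.times_min)):
            base.values.update(other.values)
            base.labels.update(other.labels)
    return base


# ---------------------------------------------------------------------------
# packaged experiments

def run_tracking_trial(seed: int, duration_min: float = 50.0,
                       period_s: float = 60.0,
                       drift_sigma_um: float = 0.15,
                       snr: float | None = 20.0) -> dict:
    """One closed-loop tracking run on a drifting specimen.

    A single position is imaged every ``period_s`` for ``duration_min``
    while the specimen random-walks with per-frame step ``drift_sigma_um``
    on all three axes. Returns the final and maximal lateral tracking
    error (px) and final focal error (um) against ground truth.
    """
    plan = SessionPlan(steps=[
        TimelineStep("P0", "imaging", start_s=0.0,
                     duration_s=duration_min * 60.0, period_s=period_s),
    ])
    config = SessionConfig(
        drift=DriftModel(sigma_um=(drift_sigma_um,) * 3),
        snr=snr,
    )
    result = run_session(plan, [VirtualPosition("P0")], config=config,
                         seed=seed)
    img = result.log[result.log["action"] == "imaging"]
    return {
        "n_frames": len(img),
        "final_error_px": float(img["tracking_error_px"].iloc[-1]),
        "max_error_px": float(img["tracking_error_px"].max()),
        "final_focal_error_um": float(img["focal_error_um"].iloc[-1]),
    }


def simulate_plasticity_cohort(n_spines: int = 24,
                               plasticity: PlasticityModel | None = None,
                               snr: float = 10.0,
                               seed: int = 0,
                               times_min: np.ndarray | None = None,
                               scope: Microscope | None = None):
    """Image a cohort of stimulated spines and quantify their plasticity.

    Each spine is an independent phantom (stimulated + adjacent spine +
    dendrite control) imaged as a time-lapse of Z-stacks with uncaging
    at t = 0; stacks are sum-projected, ROI-integrated and normalized to
    the pre-uncaging baseline. Sampling is denser during the transient
    phase (every minute through +10 min) than during the sustained
    phase (every 2 min), the way a real timeline would be drawn up.

    Returns ``(series, ground_truth_dict)`` where the ground truth
    holds the generative window means the recovery is judged against.
    """
    from .quantify import SUSTAINED_WINDOW_MIN, TRANSIENT_WINDOW_MIN

    plasticity = plasticity or PlasticityModel()
    scope = scope or Microscope()
    if times_min is None:
        times_min = np.concatenate([
            np.arange(-5.0, 10.0 + 0.5, 1.0),
            np.arange(12.0, 30.0 + 0.5, 2.0),
        ])
    rng = np.random.default_rng(seed)
    af = AutofocusConfig()
    k = int(round(af.range_um / af.step_um))

    traces: dict[str, np.ndarray] = {}
    labels: dict[str, str] = {}
    for i in range(n_spines):
        phantom = default_phantom(scope)
        noise = shot_noise_for_snr(phantom, scope, snr)
        rois, bg_roi = split_background(default_rois(phantom, scope))
        raws = {r.label: [] for r in rois}
        for t in times_min:
            vf = np.ones(len(phantom.spines))
            vf[0] = spine_volume_factor(plasticity, float(t))
            z_positions = np.arange(-k, k + 1) * af.step_um
            proj = np.zeros((scope.frame_px, scope.frame_px))
            for z in z_positions:
                proj += render_slice(phantom, scope, float(z),
                                     volume_factors=vf, noise=noise, rng=rng)
            for r in rois:
                raws[r.label].append(integrate_roi(proj, r, background_roi=bg_roi))
        for label, vals in raws.items():
            obj = f"spine{i:02d}/{label}"
            traces[obj] = np.asarray(vals)
            labels[obj] = label

    series = normalize_series(times_min, traces, labels)

    def _gen_mean(window):
        lo, hi = window
        sel = (times_min >= lo) & (times_min <= hi)
        return float(np.mean(
            spine_volume_factor(plasticity, times_min[sel]) - 1.0
        ))

    truth = {
        "transient_change": _gen_mean(TRANSIENT_WINDOW_MIN),
        "sustained_change": _gen_mean(SUSTAINED_WINDOW_MIN),
        "model": plasticity,
    }
    return series, truth
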