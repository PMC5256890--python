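"""Virtual microscope: rendering physics, drift, plasticity, ground truth."""

import dataclasses

import numpy as np
import pytest

from spinetrack.autofocus import best_focus
from spinetrack.drift import estimate_shift
from spinetrack.focus_measures import compute_focus
from spinetrack.synthetic import (DriftModel, DriftState, Microscope,
                                  NoiseModel, Phantom, PlasticityModel, Spine,
                                  acquire_stack, default_phantom,
                                  make_benchmark_dataset, read_noise_for_snr,
                                  render_slice, spine_volume_factor,
                                  step_drift)


def test_volume_factor_time_course():
    m = PlasticityModel(t0_min=0.0, a_trans=2.0, tau_trans_min=1.5,
                        a_sust=0.6)
    assert spine_volume_factor(m, -3.0) == 1.0
    assert spine_volume_factor(m, 0.0) == pytest.approx(3.6)
    assert spine_volume_factor(m, 1e6) == pytest.approx(1.6)
    assert spine_volume_factor(m, 1.5) == pytest.approx(
        1.6 + 2.0 * np.exp(-1.0))


def test_drift_stepping():
    still = step_drift(DriftState(), DriftModel())
    assert still.offset_um == (0.0, 0.0, 0.0)
    state = DriftState()
    creep = DriftModel(creep_um_per_min=(1.0, 0.0, 0.0))
    for _ in range(10):
        state = step_drift(state, creep, dt_min=1.0)
    assert state.offset_um[0] == pytest.approx(10.0)
    assert state.t_min == pytest.approx(10.0)


def test_random_walk_variance_law(rng):
    model = DriftModel(sigma_um=(0.2, 0.2, 0.2))
    n = 10_000
    steps = np.array([step_drift(DriftState(), model, rng=rng).offset_um
                      for _ in range(n)])
    var = steps.var(axis=0)
    assert np.all(np.abs(var - 0.04) < 0.05 * 0.04 * 3)  # ~3 sigma band
    with pytest.raises(ValueError):
        step_drift(DriftState(), model)  # random walk needs a generator


def test_zero_phantom_renders_black(scope):
    empty = Phantom(dendrite_intensity=0.0, spines=())
    img = render_slice(empty, scope, 0.0)
    assert np.all(img == 0.0)


def test_blur_conserves_total_intensity(scope, phantom):
    a = render_slice(phantom, scope, 0.0, defocus_um=0.0)
    b = render_slice(phantom, scope, 0.0, defocus_um=2.0)
    assert b.sum() == pytest.approx(a.sum(), rel=1e-3)


def test_defocus_reduces_sharpness(scope, phantom):
    sharp = render_slice(phantom, scope, 0.0, defocus_um=0.0)
    blurred = render_slice(phantom, scope, 0.0, defocus_um=3.0)
    assert compute_focus(sharp, "BREN") > compute_focus(blurred, "BREN")


def test_spine_mass_linear_in_volume_factor(scope):
    """Integrated spine fluorescence tracks the volume factor to ±2%."""
    lone = Phantom(
        dendrite_row_um=6.4, dendrite_intensity=0.0,
        spines=(Spine(anchor_um=6.4, side=1),),
    )
    base = None
    for vf in (1.0, 1.3, 2.0, 3.6):
        total = sum(
            render_slice(lone, scope, z, volume_factors=[vf]).sum()
            for z in np.arange(-3, 4) * 0.5
        )
        if base is None:
            base = total
        assert total / base == pytest.approx(vf, rel=0.02)


def test_acquire_stack_ground_truth_and_closed_loops(scope, phantom):
    stack, gt = acquire_stack(phantom, scope, 0.0, 1.5, 0.5)
    assert gt.true_focal_index == 3  # no drift: middle slice
    assert len(stack) == 7 and stack.step_um == pytest.approx(0.5)

    # lateral drift closes the loop with the shift estimator
    drift = DriftState(offset_um=(0.2, -0.1, 0.0))  # +2 px, -1 px
    moved, gt2 = acquire_stack(phantom, scope, 0.0, 1.5, 0.5, drift=drift)
    est = estimate_shift(stack.slices[3], moved.slices[3])
    assert est.as_tuple() == (2, -1)
    assert gt2.lateral_offset_px == pytest.approx((2.0, -1.0))

    # axial drift moves the in-focus slice by one step
    axial = DriftState(offset_um=(0.0, 0.0, 0.5))
    shifted, gt3 = acquire_stack(phantom, scope, 0.0, 1.5, 0.5, drift=axial)
    assert gt3.true_focal_index == 4
    assert best_focus(shifted, "BREN") == 4


def test_noise_model_validation_and_seeding(scope, phantom):
    with pytest.raises(ValueError):
        NoiseModel(read_sigma=-1.0)
    noise = read_noise_for_snr(phantom, scope, 10.0)
    clean = render_slice(phantom, scope, 0.0)
    assert noise.read_sigma == pytest.approx(clean.max() / 10.0)
    assert noise.background == pytest.approx(3.0 * noise.read_sigma)
    with pytest.raises(ValueError):
        render_slice(phantom, scope, 0.0, noise=noise)  # rng required
    a = render_slice(phantom, scope, 0.0, noise=noise,
                     rng=np.random.default_rng(5))
    b = render_slice(phantom, scope, 0.0, noise=noise,
                     rng=np.random.default_rng(5))
    assert np.array_equal(a, b)
    assert np.all(a >= 0)


def test_shot_noise_variance_scales_with_signal(rng):
    noise = NoiseModel(photon_scale=50.0)
    flat_lo = np.full((64, 64), 1.0)
    flat_hi = np.full((64, 64), 4.0)
    lo = noise.apply(flat_lo, rng).var()
    hi = noise.apply(flat_hi, rng).var()
    assert hi / lo == pytest.approx(4.0, rel=0.15)


def test_dataset_generation_is_seed_deterministic(scope):
    ds1 = make_benchmark_dataset(3, 5, np.random.default_rng(9), scope=scope)
    ds2 = make_benchmark_dataset(3, 5, np.random.default_rng(9), scope=scope)
    for (s1, t1, _), (s2, t2, _) in zip(ds1, ds2):
        assert t1 == t2
        assert np.array_equal(s1.slices, s2.slices)
    targets = [t for _, t, _ in make_benchmark_dataset(
        30, 7, np.random.default_rng(1), scope=scope)]
    assert len(set(targets)) > 1  # annotations spread across the stack
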