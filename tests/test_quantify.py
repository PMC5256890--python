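"""Sum projection, ROI integration, normalization and phase statistics."""

import math

import numpy as np
import pytest

from spinetrack.core import ZStack
from spinetrack.quantify import (QuantROI, integrate_roi, normalize_series,
                                 phase_stats, stats_to_frame, sum_project)


def oval(r0, c0, a=3.0, b=3.0, label="stimulated"):
    return QuantROI(kind="oval", label=label, center=(r0, c0),
                    semi_axes=(a, b))


def test_sum_project_linearity():
    one = np.arange(36, dtype=float).reshape(6, 6)
    stack = ZStack(slices=np.stack([one, one]))
    assert np.array_equal(sum_project(stack), 2 * one)
    assert np.array_equal(sum_project(one[None]), one)


def test_integrate_roi_constant_and_background():
    img = np.full((12, 12), 3.0)
    roi = oval(6, 6)
    k = roi.mask(img.shape).sum()
    assert integrate_roi(img, roi) == pytest.approx(3.0 * k)
    bg = oval(3, 3, 2, 2, label="background")
    assert integrate_roi(img, roi, background_roi=bg) == pytest.approx(0.0)


def test_integrate_roi_captures_enclosed_square():
    img = np.zeros((10, 10))
    img[4:7, 4:7] = 2.0
    roi = oval(5, 5, 3.2, 3.2)
    assert integrate_roi(img, roi) == pytest.approx(2.0 * 9)


def test_integrate_roi_additive_and_linear(rng):
    img = rng.random((20, 20)) * 5
    left = QuantROI(kind="polygon", label="dendrite",
                    vertices=((0, 0), (0, 9.5), (19.5, 9.5), (19.5, 0)))
    right = QuantROI(kind="polygon", label="dendrite",
                     vertices=((0, 9.5), (0, 19.5), (19.5, 19.5), (19.5, 9.5)))
    whole = QuantROI(kind="polygon", label="dendrite",
                     vertices=((0, 0), (0, 19.5), (19.5, 19.5), (19.5, 0)))
    assert integrate_roi(img, left) + integrate_roi(img, right) == \
        pytest.approx(integrate_roi(img, whole))
    assert integrate_roi(3 * img, whole) == pytest.approx(
        3 * integrate_roi(img, whole))


def test_polygon_and_oval_validation():
    with pytest.raises(ValueError):
        QuantROI(kind="oval", label="stimulated", center=(2, 2),
                 semi_axes=(0, 1))
    with pytest.raises(ValueError):
        QuantROI(kind="polygon", label="dendrite", vertices=((0, 0), (1, 1)))
    with pytest.raises(ValueError):
        QuantROI(kind="oval", label="nope", center=(2, 2), semi_axes=(1, 1))
    tiny = QuantROI(kind="oval", label="adjacent", center=(50, 50),
                    semi_axes=(0.2, 0.2))
    with pytest.raises(ValueError):
        tiny.mask((8, 8))  # covers no pixel centers / out of frame


def test_normalize_series_basics():
    times = np.array([-2.0, -1.0, 1.0, 2.0])
    series = normalize_series(times, {"a": [4, 4, 8, 8], "b": [2, 2, 2, 2]},
                              {"a": "stimulated", "b": "dendrite"})
    assert np.allclose(series.values["a"], [1, 1, 2, 2])
    assert np.allclose(series.values["b"], 1.0)
    # idempotent on an already-normalized trace
    again = normalize_series(times, series.values, series.labels)
    assert np.allclose(again.values["a"], series.values["a"])
    df = series.to_frame()
    assert set(df.columns) == {"time_min", "object_id", "label",
                               "normalized_volume", "volume_change"}
    assert np.allclose(df["volume_change"], df["normalized_volume"] - 1)


def test_normalize_series_errors():
    with pytest.raises(ValueError):
        normalize_series([1.0, 2.0], {"a": [1, 2]})  # no pre-uncaging points
    with pytest.raises(ValueError):
        normalize_series([-1.0, 1.0], {"a": [0.0, 1.0]})  # zero baseline


def hand_pooled_t(x, y):
    """Textbook pooled-variance two-sample t, evaluated from scratch."""
    nx, ny = len(x), len(y)
    mx, my = sum(x) / nx, sum(y) / ny
    ssx = sum((v - mx) ** 2 for v in x)
    ssy = sum((v - my) ** 2 for v in y)
    sp2 = (ssx + ssy) / (nx + ny - 2)
    return (mx - my) / math.sqrt(sp2 * (1 / nx + 1 / ny))


def _series_from_window_values(stim, dend):
    """Objects whose [1,3]-min window means equal the given values."""
    times = np.array([-1.0, 2.0])
    traces, labels = {}, {}
    for i, v in enumerate(stim):
        traces[f"s{i}"] = [1.0, v]
        labels[f"s{i}"] = "stimulated"
    for i, v in enumerate(dend):
        traces[f"d{i}"] = [1.0, v]
        labels[f"d{i}"] = "dendrite"
    return normalize_series(times, traces, labels)


def test_phase_stats_identical_groups_give_null_result():
    series = _series_from_window_values([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
    res = [r for r in phase_stats(series, windows=[(1.0, 3.0)])
           if r.group == "stimulated"]
    assert res[0].t_statistic == pytest.approx(0.0)
    assert res[0].p_value == pytest.approx(1.0)


def test_phase_stats_matches_hand_evaluated_t():
    series = _series_from_window_values([1.0, 2.0, 3.0], [4.0, 5.0, 6.0])
    res = [r for r in phase_stats(series, windows=[(1.0, 3.0)])
           if r.group == "stimulated"][0]
    assert res.t_statistic == pytest.approx(
        hand_pooled_t([0.0, 1.0, 2.0], [3.0, 4.0, 5.0])
    )
    assert res.t_statistic == pytest.approx(-3.0 / math.sqrt(2.0 / 3.0))
    assert res.n_group == res.n_control == 3
    frame = stats_to_frame([res])
    assert frame.loc[0, "p_value"] == pytest.approx(res.p_value)


def test_phase_stats_requires_samples_and_groups():
    series = _series_from_window_values([1.0, 2.0], [1.0, 2.0])
    with pytest.raises(ValueError):
        phase_stats(series, windows=[(50.0, 60.0)])  # empty window
    lone = normalize_series([-1.0, 2.0], {"a": [1, 2]}, {"a": "stimulated"})
    with pytest.raises(ValueError):
        phase_stats(lone)  # no dendrite control group


def test_p_values_uniform_under_the_null(rng):
    """Monte-Carlo calibration: same-distribution groups give U[0,1] p."""
    from scipy import stats as sps

    reps, n = 10_000, 6
    x = rng.normal(size=(reps, n))
    y = rng.normal(size=(reps, n))
    _, p = sps.ttest_ind(x, y, axis=1, equal_var=True)
    grid = np.sort(p)
    ks = np.max(np.abs(grid - (np.arange(1, reps + 1) / reps)))
    assert ks < 0.02
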