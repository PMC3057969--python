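"""Filtering, velocity, segmentation, temporal parameters, resampling, and
the within-subject ANOVAs."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

import pointkin as pk
from pointkin.kinematics import (
    TEMPORAL_PARAMETERS,
    exponential_filter,
    pointwise_condition_anova,
    process_trial,
    repeated_measures_anova,
    resample_trajectory,
    segment_movement,
    tangential_velocity,
    temporal_anova,
)
from pointkin.kinematics import _rm_anova_arrays

FS = 400.0


# ------------------------------------------------------------ filtering

def test_filter_constant_series_is_fixed_point():
    out = exponential_filter(np.array([5.0, 5.0, 5.0]), 0.1)
    np.testing.assert_array_equal(out, [5.0, 5.0, 5.0])


@pytest.mark.parametrize("recursive", [True, False])
def test_filter_coefficient_one_is_identity(rng, recursive):
    x = rng.normal(size=50)
    np.testing.assert_allclose(
        exponential_filter(x, 1.0, recursive=recursive), x, atol=1e-12
    )


def test_filter_step_response_geometric():
    # recursive smoother on a unit step: k-th post-step value is 1 - 0.9^k
    x = np.r_[0.0, np.ones(30)]
    out = exponential_filter(x, 0.1)
    k = np.arange(1, 31)
    np.testing.assert_allclose(out[1:], 1.0 - 0.9**k, atol=1e-12)
    assert out[0] == x[0]


def test_filter_two_tap_literal_form():
    x = np.array([0.0, 1.0, 1.0, 1.0])
    np.testing.assert_allclose(
        exponential_filter(x, 0.1, recursive=False), [0.0, 0.1, 1.0, 1.0]
    )


def test_filter_applies_per_column(rng):
    x = rng.normal(size=(40, 3))
    out = exponential_filter(x, 0.2)
    for j in range(3):
        np.testing.assert_allclose(out[:, j], exponential_filter(x[:, j], 0.2))


def test_filter_rejects_bad_inputs():
    with pytest.raises(ValueError):
        exponential_filter(np.array([]), 0.1)
    with pytest.raises(ValueError):
        exponential_filter(np.arange(3.0), 0.0)


@given(
    st.lists(st.floats(-1e3, 1e3), min_size=2, max_size=60),
    st.floats(0.05, 1.0),
)
def test_filter_never_increases_total_variation(values, coefficient):
    x = np.asarray(values)
    out = exponential_filter(x, coefficient)
    tv = lambda s: np.abs(np.diff(s)).sum()
    assert tv(out) <= tv(x) + 1e-6


# ------------------------------------------------------------- velocity

def test_velocity_uniform_straight_line_motion():
    # 100 mm per sample interval at 400 Hz -> 40,000 mm/s everywhere
    traj = np.arange(20.0)[:, None] * np.array([100.0, 0.0, 0.0])
    v = tangential_velocity(traj, FS)
    np.testing.assert_allclose(v, 40_000.0)


def test_velocity_circular_motion_matches_r_omega():
    r, omega = 50.0, 2 * np.pi
    t = np.arange(0, 1, 1 / FS)
    traj = np.column_stack([r * np.cos(omega * t), r * np.sin(omega * t), 0 * t])
    v = tangential_velocity(traj, FS)
    np.testing.assert_allclose(v[1:-1], r * omega, rtol=1e-3)


def test_velocity_stationary_marker_is_zero():
    traj = np.tile([1.0, 2.0, 3.0], (10, 1))
    np.testing.assert_array_equal(tangential_velocity(traj, FS), 0.0)


def test_velocity_needs_two_samples():
    with pytest.raises(ValueError):
        tangential_velocity(np.zeros((1, 3)), FS)


# --------------------------------------------------------- segmentation

def test_segment_triangular_profile_enumerated():
    # v = 0,5,...,100,...,5,0 over 41 samples; threshold 5% of 100 = 5
    v = np.r_[np.arange(0.0, 101.0, 5.0), np.arange(95.0, -1.0, -5.0)]
    seg = segment_movement(v, 0.05)
    assert seg.onset_index == 1  # first sample >= 5
    assert seg.peak_index == 20
    assert seg.offset_index == 40  # first sample after peak < 5
    assert seg.valid and seg.peak_count == 1


@given(st.floats(0.01, 1e6))
def test_segment_invariant_to_velocity_rescaling(scale):
    tau = np.linspace(0, 1, 101)
    v = 30 * tau**2 * (1 - tau) ** 2
    a, b = segment_movement(v), segment_movement(v * scale)
    assert (a.onset_index, a.offset_index, a.peak_count) == (
        b.onset_index,
        b.offset_index,
        b.peak_count,
    )


def test_segment_two_equal_lobes_invalid():
    tau = np.linspace(0, 1, 80)
    lobe = np.sin(np.pi * tau) ** 2
    v = np.r_[lobe, 0.0, lobe]
    seg = segment_movement(v, 0.05, peak_multiplicity_frac=0.5)
    assert seg.peak_count == 2
    assert not seg.valid


def test_segment_offset_clipped_when_velocity_stays_high():
    v = np.r_[np.linspace(0, 100, 30), np.full(20, 60.0)]
    seg = segment_movement(v)
    assert seg.offset_clipped
    assert seg.offset_index == v.size - 1


def test_segment_rejects_flat_zero_velocity():
    with pytest.raises(ValueError, match="no movement"):
        segment_movement(np.zeros(50))


def test_symmetric_bell_ttp_is_half_duration():
    tau = np.linspace(0, 1, 241)
    v = 30 * tau**2 * (1 - tau) ** 2
    seg = segment_movement(v)
    dur = seg.offset_index - seg.onset_index
    ttp = seg.peak_index - seg.onset_index
    assert abs(ttp - dur / 2) <= 1.0


# ------------------------------------------------- temporal parameters

def _noise_free_trial(**overrides):
    defaults = dict(marker_jitter_mm=0.0, duration_jitter_ms=0.0, seed=5)
    defaults.update(overrides)
    config = pk.GeneratorConfig(**defaults)
    return config, *pk.generate_trial(config, 0, 0, 1, pk.Condition.NCP, "glass")


def test_meanvel_is_distance_over_duration():
    config, trial, truth = _noise_free_trial()
    movement, _, _ = process_trial(trial, pk.RunConfig())
    assert movement.valid
    np.testing.assert_allclose(
        movement.meanvel_mm_s,
        movement.distance_mm / (movement.dur_ms / 1000.0),
        rtol=1e-12,
    )
    # ~300 mm straight-line distance over ~600 ms -> ~500 mm/s
    config2, trial2, _ = _noise_free_trial(
        targets=("glass",),
        target_positions={"glass": (0.0, -300.0, 0.0)},
        arc_height_mm=0.0,
        endpoint_models={c: pk.EndpointModel(90.0, scale_mm=0.0) for c in pk.CONDITIONS},
    )
    # identity filter: the threshold-to-threshold span covers all but ~0.4%
    # of the 300 mm path, so meanvel ~ 300 mm / 0.6 s = 500 mm/s
    m2, _, _ = process_trial(trial2, pk.RunConfig(filter_coefficient=1.0))
    assert m2.meanvel_mm_s == pytest.approx(m2.distance_mm / (m2.dur_ms / 1e3))
    assert m2.distance_mm == pytest.approx(300.0, abs=2.0)
    assert m2.meanvel_mm_s == pytest.approx(500.0, rel=0.02)


def test_crt_equals_rt_when_release_coincides_with_onset():
    _, trial, _ = _noise_free_trial()
    movement, _, _ = process_trial(trial, pk.RunConfig())
    trial.led2_on = np.arange(trial.n_samples) < movement.onset_index
    again, _, _ = process_trial(trial, pk.RunConfig())
    assert again.cRT_ms == pytest.approx(trial.rt_raw_ms, abs=1e-9)


def test_crt_adds_release_to_onset_gap():
    _, trial, truth = _noise_free_trial()
    movement, _, _ = process_trial(trial, pk.RunConfig())
    gap_ms = (trial.t[movement.onset_index] - trial.t[trial.release_index()]) * 1e3
    assert gap_ms > 0
    assert movement.cRT_ms == pytest.approx(trial.rt_raw_ms + gap_ms)


def test_onset_before_release_flagged_invalid():
    _, trial, _ = _noise_free_trial()
    movement, _, _ = process_trial(trial, pk.RunConfig())
    # move the release after the detected onset
    trial.led2_on = np.arange(trial.n_samples) < (movement.onset_index + 20)
    flagged, _, _ = process_trial(trial, pk.RunConfig())
    assert not flagged.valid
    assert "precedes button release" in flagged.invalid_reason


def test_segmented_movement_invariants_on_synthetic_trials():
    config = pk.GeneratorConfig(seed=17)
    for i in range(25):
        trial, _ = pk.generate_trial(config, 0, i, 1, pk.Condition.LEFT_CP, "glass")
        m, filt, _ = process_trial(trial, pk.RunConfig())
        assert m.onset_index < m.peak_index <= m.offset_index
        assert 0 < m.ttp_ms <= m.dur_ms
        assert m.meanvel_mm_s <= m.maxvel_mm_s
        path = np.linalg.norm(
            np.diff(filt[m.onset_index : m.offset_index + 1], axis=0), axis=1
        ).sum()
        assert m.distance_mm <= path + 1e-9


# ----------------------------------------------------------- resampling

def test_resample_straight_line_equally_spaced():
    t = np.arange(50) / FS
    traj = np.linspace([0, 0, 0], [98, 0, 0], 50)
    pts = resample_trajectory(traj, t, 0, 49, 20)
    assert pts.shape == (20, 3)
    steps = np.diff(pts, axis=0)
    np.testing.assert_allclose(steps, np.tile(steps[0], (19, 1)), atol=1e-9)
    np.testing.assert_allclose(pts[-1], traj[49], atol=1e-9)


def test_resample_rejects_tiny_requests():
    t = np.arange(10) / FS
    traj = np.zeros((10, 3))
    with pytest.raises(ValueError):
        resample_trajectory(traj, t, 0, 9, 1)
    with pytest.raises(ValueError):
        resample_trajectory(traj, t, 4, 4, 20)


@given(st.integers(0, 2**31 - 1))
def test_resampled_chord_never_exceeds_raw_path_length(seed):
    rng = np.random.default_rng(seed)
    n = 60
    traj = np.cumsum(rng.normal(size=(n, 3)), axis=0)
    t = np.arange(n) / FS
    pts = resample_trajectory(traj, t, 0, n - 1, 20)
    chord = np.linalg.norm(pts[-1] - traj[0])
    path = np.linalg.norm(np.diff(traj, axis=0), axis=1).sum()
    assert chord <= path + 1e-9


# --------------------------------------------------------------- ANOVA

def test_rm_anova_identical_condition_means_gives_f_zero():
    y = np.tile(np.arange(6.0)[:, None], (1, 3))  # subjects differ, conditions don't
    F, p = _rm_anova_arrays(y[None])
    assert F[0] == 0.0 and p[0] == 1.0


def test_rm_anova_matches_statsmodels(rng):
    from statsmodels.stats.anova import AnovaRM

    y = rng.normal(size=(8, 3)) + np.array([0.0, 0.4, 0.1])
    F, p = _rm_anova_arrays(y[None])
    long = pd.DataFrame(
        {
            "participant": np.repeat(np.arange(8), 3),
            "condition": np.tile(["a", "b", "c"], 8),
            "value": y.ravel(),
        }
    )
    table = AnovaRM(long, "value", "participant", within=["condition"]).fit().anova_table
    assert F[0] == pytest.approx(table["F Value"].iloc[0], rel=1e-8)
    assert p[0] == pytest.approx(table["Pr > F"].iloc[0], rel=1e-8)


def test_repeated_measures_anova_missing_condition_named():
    df = pd.DataFrame(
        {
            "participant": ["p1", "p1", "p2"],
            "condition": ["a", "b", "a"],
            "value": [1.0, 2.0, 3.0],
        }
    )
    with pytest.raises(ValueError, match="p2"):
        repeated_measures_anova(df)


def test_pointwise_anova_null_calibration(rng):
    # under no condition effect, the per-point flag rate stays near alpha
    y = rng.normal(size=(500, 10, 3))
    _, p = _rm_anova_arrays(y)
    rate = (p < 0.05).mean()
    assert 0.02 < rate < 0.09


def test_pointwise_anova_flags_shifted_condition(rng):
    rows = []
    for pid in range(8):
        for cond in ("a", "b", "c"):
            for trial in range(10):
                for point in range(1, 21):
                    value = rng.normal(scale=1.0)
                    if cond == "b" and point >= 15:
                        value += 3.0
                    rows.append(
                        {
                            "participant": f"P{pid}",
                            "condition": cond,
                            "point": point,
                            "value": value,
                        }
                    )
    table = pointwise_condition_anova(pd.DataFrame(rows), conditions=("a", "b", "c"))
    assert len(table) == 20
    assert bool(table.loc[table["point"] == 20, "significant"].iloc[0])
    assert not bool(table.loc[table["point"] == 1, "significant"].iloc[0])


def test_temporal_anova_targeted_perturbation(rng):
    rows = []
    for pid in range(10):
        for cond in pk.CONDITIONS:
            for _ in range(15):
                row = {"participant": f"P{pid}", "condition": cond}
                for name in TEMPORAL_PARAMETERS:
                    row[name] = rng.normal(loc=500.0, scale=30.0)
                if cond is pk.Condition.NCP:
                    row["dur_ms"] *= 1.5
                rows.append(row)
    table = temporal_anova(pd.DataFrame(rows)).set_index("parameter")
    assert bool(table.loc["dur_ms", "significant"])
    others = table.drop(index="dur_ms")
    assert (others["p"] > 0.01).all()
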