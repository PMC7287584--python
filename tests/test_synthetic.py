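import dataclasses

import numpy as np
import pytest
from scipy import signal as sps

from gaitvar.forceplate import detect_force_peaks
from gaitvar.synthetic import (
    GaitSimParams,
    GroundTruth,
    earth_vertical_acceleration,
    generate_stride_plan,
    simulate_session,
    synthesize_ankle_imu,
    synthesize_forceplate,
    synthesize_waist_imu,
)


def test_zero_sd_gives_constant_durations():
    params = GaitSimParams(stride_sd_ms=0.0, duration_s=30.0, seed=1)
    truth = generate_stride_plan(params)
    np.testing.assert_allclose(truth.stride_durations_ms, 1040.0, rtol=1e-12)


def test_default_walk_stride_count():
    truth = generate_stride_plan(GaitSimParams(seed=4))
    # a 3-min walk at ~1040 ms per stride yields ~173 right heel-strikes
    assert abs(len(truth.right_hs) - 173) <= 3


def test_truth_invariants():
    truth = generate_stride_plan(GaitSimParams(seed=9, duration_s=60.0))
    np.testing.assert_allclose(np.diff(truth.right_hs) * 1000.0,
                               truth.stride_durations_ms, rtol=1e-12)
    for arr in (truth.right_hs, truth.left_hs, truth.right_to, truth.left_to):
        assert np.all(np.diff(arr) > 0)


def test_stride_sd_distribution_over_seeds():
    """Monte-Carlo check of the stated stride-duration process: the mean
    sample SD over 50 independent plans is within 5% of the 19.6 ms target."""
    sds = [
        np.std(generate_stride_plan(GaitSimParams(seed=s)).stride_durations_ms, ddof=1)
        for s in range(50)
    ]
    assert np.mean(sds) == pytest.approx(19.6, rel=0.05)


def test_ar1_autocorrelation_sign():
    d = generate_stride_plan(GaitSimParams(seed=3, ar1_phi=0.8)).stride_durations_ms
    d = d - d.mean()
    lag1 = np.dot(d[:-1], d[1:]) / np.dot(d, d)
    assert lag1 > 0.5


def test_force_mean_is_body_weight(noiseless_params, noiseless_session):
    force = noiseless_session[0]
    assert force.fz.mean() == pytest.approx(noiseless_params.body_weight_N, rel=0.05)


def test_force_gate_fires_each_step(noiseless_params, noiseless_session):
    """Every step produces supra-threshold force runs lasting beyond 2.5 ms."""
    force, _, _, truth = noiseless_session
    runs = detect_force_peaks(force)
    n_steps = len(truth.right_hs) + len(truth.left_hs)
    assert n_steps <= len(runs) <= 3 * n_steps
    # at least one run peak within 50 ms after every heel-strike
    peak_times = np.array([pt for _, pt in runs])
    for hs in np.concatenate([truth.right_hs, truth.left_hs]):
        assert np.any((peak_times >= hs) & (peak_times <= hs + 0.05))


def test_zero_duration_walk_is_empty():
    params = GaitSimParams(duration_s=0.0, seed=0)
    truth = generate_stride_plan(params)
    force = synthesize_forceplate(truth, params)
    assert len(force) == 0


def _static_truth():
    empty = np.empty(0)
    return GroundTruth(empty, empty, empty, empty, empty)


def test_static_waist_level_shows_gravity_only():
    params = GaitSimParams(waist_tilt_deg=0.0, duration_s=5.0, noise_acc_g=0.0, seed=0)
    imu = synthesize_waist_imu(_static_truth(), params)
    np.testing.assert_allclose(imu.acc.mean(axis=0), [0, 0, 1], atol=1e-9)
    np.testing.assert_allclose(imu.gyr, 0, atol=1e-9)


def test_static_waist_90deg_tilt_rotates_gravity():
    params = GaitSimParams(waist_tilt_deg=90.0, duration_s=5.0, noise_acc_g=0.0, seed=0)
    imu = synthesize_waist_imu(_static_truth(), params)
    np.testing.assert_allclose(imu.acc.mean(axis=0), [0, 1, 0], atol=1e-9)


def test_waist_peak_count_matches_heelstrikes(noiseless_params, noiseless_session):
    _, waist, _, truth = noiseless_session
    av = earth_vertical_acceleration(truth, noiseless_params, waist.t)
    peaks, _ = sps.find_peaks(av, height=0.25, distance=int(0.3 * 400))
    assert len(peaks) == len(truth.right_hs) + len(truth.left_hs)


def test_ankle_gyro_periodic_at_zero_sd():
    params = GaitSimParams(stride_sd_ms=0.0, duration_s=30.0, noise_acc_g=0.0, seed=2)
    truth = generate_stride_plan(params)
    imu = synthesize_ankle_imu(truth, params)
    period = int(round(1.040 * params.imu_rate_hz))
    gy = imu.gyr[:, 1]
    lo = int(2.0 * params.imu_rate_hz)
    hi = int(25.0 * params.imu_rate_hz)
    # periodic to the 5σ truncation tail of the trough kernels (≪ 1e-2 °/s)
    np.testing.assert_allclose(gy[lo:hi], gy[lo + period : hi + period], atol=1e-3)


def test_ankle_troughs_at_truth_events(noiseless_params, noiseless_session):
    _, _, ankle, truth = noiseless_session
    gy = ankle.gyr[:, 1]
    fs = noiseless_params.imu_rate_hz
    for hs in truth.right_hs[1:-1]:
        i = int(round(hs * fs))
        w = int(0.05 * fs)
        local = gy[i - w : i + w + 1]
        assert abs((i - w + np.argmin(local)) / fs - hs) <= 1 / fs


def test_same_seed_bit_identical():
    p = GaitSimParams(seed=21, duration_s=20.0)
    s1 = simulate_session(p)
    s2 = simulate_session(p)
    for a, b in zip(s1[:3], s2[:3]):
        np.testing.assert_array_equal(a.t, b.t)
        for f in ("fz", "fy", "fx") if hasattr(a, "fz") else ("acc", "gyr"):
            np.testing.assert_array_equal(getattr(a, f), getattr(b, f))
    s3 = simulate_session(dataclasses.replace(p, seed=22))
    assert not np.array_equal(s1[0].fz, s3[0].fz)


def test_param_validation():
    with pytest.raises(ValueError):
        GaitSimParams(mean_stride_ms=-1)
    with pytest.raises(ValueError):
        GaitSimParams(duty_factor=0.9)
    with pytest.raises(ValueError):
        GaitSimParams(ar1_phi=1.0)
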