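import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import signal as sps

from gaitvar.events import HS, TO, EventSeries
from gaitvar.imu_events import (
    detect_ankle_events,
    detect_waist_heelstrikes,
    pair_ankle_events,
    ricker_kernel,
    zero_lag_lowpass,
)
from gaitvar.kinematics import ScalarSeries
from gaitvar.pipeline import waist_vertical
from gaitvar.strides import match_events


def _series(values, fs=400.0, kind="vertical_acc_g"):
    return ScalarSeries(np.asarray(values, float), fs, kind)


class TestRickerKernel:
    def test_shape(self):
        k = ricker_kernel(16.0, 400.0)
        psi = k.samples
        sigma = 1.0 / (np.pi * 16.0 * np.sqrt(2.0))
        center = len(psi) // 2
        assert np.argmax(psi) == center
        # the zero crossing at +σ falls between the bracketing samples
        i_floor = int(sigma * 400.0)
        assert psi[center + i_floor] > 0 > psi[center + i_floor + 1]
        np.testing.assert_allclose(psi, psi[::-1], atol=1e-12)  # symmetry

    def test_zero_sum(self):
        k = ricker_kernel(16.0, 400.0)
        assert abs(k.samples.sum()) < 1e-6 * np.abs(k.samples).max()

    def test_spectral_peak_at_requested_frequency(self):
        k = ricker_kernel(16.0, 400.0)
        n = 4096
        spec = np.abs(np.fft.rfft(k.samples, n))
        f = np.fft.rfftfreq(n, 1 / 400.0)
        assert f[np.argmax(spec)] == pytest.approx(16.0, abs=1.0)

    def test_nyquist_precondition(self):
        with pytest.raises(ValueError):
            ricker_kernel(250.0, 400.0)


class TestWaistDetector:
    def test_sinusoid_one_event_per_cycle(self):
        t = np.arange(0, 20, 1 / 400.0)
        ev = detect_waist_heelstrikes(_series(np.sin(2 * np.pi * 1.0 * t)))
        assert abs(len(ev) - 20) <= 1

    def test_flat_signal_empty(self):
        ev = detect_waist_heelstrikes(_series(np.zeros(4000)))
        assert len(ev) == 0

    def test_noiseless_walk_recovery(self, noiseless_session):
        _, waist, _, truth = noiseless_session
        vacc = waist_vertical(waist)
        ev = detect_waist_heelstrikes(vacc)
        true_hs = truth.all_heelstrikes()
        pairs = match_events(true_hs, ev.times, tol_s=0.03)
        assert len(pairs) == len(true_hs)
        assert len(ev) == len(true_hs)

    def test_amplitude_scale_invariance(self, noisy_session):
        _, waist, _, _ = noisy_session
        vacc = waist_vertical(waist)
        ev1 = detect_waist_heelstrikes(vacc)
        scaled = ScalarSeries(7.3 * vacc.values, vacc.sample_rate, vacc.kind, vacc.t0)
        ev2 = detect_waist_heelstrikes(scaled)
        np.testing.assert_array_equal(ev1.times, ev2.times)


def test_zero_lag_filter_has_no_group_delay():
    t = np.arange(0, 10, 1 / 400.0)
    x = np.sin(2 * np.pi * 2.0 * t)
    y = zero_lag_lowpass(x, 6.0, 400.0)
    lags = sps.correlation_lags(len(y), len(x))
    lag = lags[np.argmax(sps.correlate(y, x))]
    assert abs(lag) < 1


class TestAnkleDetector:
    def test_symmetric_trough_vertex_at_center(self):
        y = np.zeros(4000)
        # one swing peak then a symmetric (4, 0, 4) trough
        y[1000:1100] = 200.0
        y[1200] = -4.0
        y[1201] = -8.0
        y[1202] = -4.0
        ev = detect_ankle_events(_series(y, kind="sagittal_gyro_dps"),
                                 parabola_halfwidth=1)
        hs = ev.select(label=HS)
        assert len(hs) == 1
        assert hs.times[0] == pytest.approx(1201 / 400.0, abs=1e-9)

    def test_constant_signal_empty(self):
        ev = detect_ankle_events(_series(np.zeros(4000), kind="sagittal_gyro_dps"))
        assert len(ev) == 0

    def test_noiseless_walk_events_within_5ms(self, noiseless_session):
        _, _, ankle, truth = noiseless_session
        sag = ScalarSeries(ankle.gyr[:, 1], 400.0, "sagittal_gyro_dps")
        ev = pair_ankle_events(detect_ankle_events(sag))
        hs = ev.select(label=HS).times
        to = ev.select(label=TO).times
        for t_true in truth.right_hs[1:]:
            assert np.min(np.abs(hs - t_true)) <= 0.005
        for t_true in truth.right_to:
            assert np.min(np.abs(to - t_true)) <= 0.005

    def test_refinement_bounded_by_halfwidth(self, noisy_session):
        _, _, ankle, _ = noisy_session
        sag = ScalarSeries(ankle.gyr[:, 1], 400.0, "sagittal_gyro_dps")
        coarse = detect_ankle_events(sag, parabola_halfwidth=0)
        fine = detect_ankle_events(sag, parabola_halfwidth=2)
        assert len(coarse) == len(fine)
        np.testing.assert_array_less(np.abs(fine.times - coarse.times),
                                     (2 + 1e-9) / 400.0)


class TestPairing:
    def _events(self, labels):
        times = np.arange(len(labels), dtype=float) * 0.3
        return EventSeries(times, np.asarray(labels, object),
                           np.full(len(labels), "right", object), "ankle")

    def test_alternating_unchanged(self):
        ev = pair_ankle_events(self._events([HS, TO, HS, TO]))
        assert list(ev.labels) == [HS, TO, HS, TO]

    def test_duplicate_keeps_earliest(self):
        ev = pair_ankle_events(self._events([HS, HS, TO]))
        assert list(ev.labels) == [HS, TO]
        assert ev.times[0] == 0.0

    @settings(derandomize=True, max_examples=100, deadline=None)
    @given(st.lists(st.sampled_from([HS, TO]), min_size=1, max_size=30))
    def test_output_always_alternates(self, labels):
        out = pair_ankle_events(self._events(labels))
        assert all(a != b for a, b in zip(out.labels, out.labels[1:]))
        # kept events are a subsequence of the input
        assert set(out.times).issubset(set(np.arange(len(labels)) * 0.3))
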