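"""Epoch segmentation, preprocessing and the normalized cross-correlation."""

import numpy as np
import pytest

from atcfes import (
    Epoch,
    make_activation_profile,
    max_xcorr,
    preprocess_epoch,
    segment_epochs,
    session_similarity,
    therapist_angle,
    xcorr_normalized,
)
from atcfes.evaluation import (
    SegmentationError,
    UndefinedCorrelationError,
    segment_bounds,
)
from atcfes.signals import AngularSignal, InvalidParameterError

FS = 80.0


def brute_force_sigma(a, b):
    """Independent double-loop evaluation of the normalized coefficient."""
    n = len(a)
    den = np.sqrt(np.dot(a, a) * np.dot(b, b))
    out = {}
    for m in range(-(n - 1), n):
        s = 0.0
        for k in range(n):
            j = k + m
            if 0 <= j < n:
                s += a[k] * b[j]
        out[m] = s / den
    return out


def pulse(center_s=1.0, width_s=0.3, dur_s=4.0):
    t = np.arange(int(dur_s * FS)) / FS
    return np.exp(-(((t - center_s) / width_s) ** 2))


class TestSegmentation:
    def test_three_bursts_give_three_epochs(self):
        env = make_activation_profile(3, 4.0, 3.0)
        ang = therapist_angle(env, arom_deg=60.0)
        epochs = segment_epochs(ang, n_reps=3)
        assert len(epochs) == 3
        # detected onsets within the guard of the true burst onsets
        bounds = segment_bounds(ang, 3)
        true_onsets = [3.0, 10.0, 17.0]
        for (lo, _), t_true in zip(bounds, true_onsets):
            assert abs(lo / FS - t_true) <= 0.5 + 0.2

    def test_flat_trace_fails(self):
        flat = AngularSignal(fs=FS, theta=np.zeros(400))
        with pytest.raises(SegmentationError):
            segment_epochs(flat, n_reps=1)

    def test_single_burst_contains_peak(self):
        theta = 60.0 * pulse(center_s=2.0)
        ang = AngularSignal(fs=FS, theta=theta)
        (epoch,) = segment_epochs(ang, n_reps=1)
        assert epoch.theta.max() == pytest.approx(theta.max())

    def test_epochs_never_overlap(self):
        env = make_activation_profile(4, 3.0, 1.0)
        ang = therapist_angle(env, arom_deg=50.0)
        bounds = segment_bounds(ang, 4, guard_s=2.0)
        for (_, hi), (lo, _) in zip(bounds, bounds[1:]):
            assert hi <= lo


class TestPreprocess:
    def test_constant_epoch_zeroed(self):
        e = Epoch(theta=np.full(100, 42.0), fs=FS)
        out = preprocess_epoch(e, arom_deg=60.0)
        assert np.all(out.theta == 0.0)

    def test_peak_normalized_to_one(self):
        theta = 30.0 + 60.0 * pulse()
        theta[:20] = 30.0  # flat resting start
        out = preprocess_epoch(Epoch(theta=theta, fs=FS), arom_deg=60.0)
        assert out.theta.max() == pytest.approx(1.0, abs=1e-6)

    def test_offset_invariance(self):
        theta = 60.0 * pulse()
        a = preprocess_epoch(Epoch(theta=theta, fs=FS), 60.0)
        b = preprocess_epoch(Epoch(theta=theta + 90.0, fs=FS), 60.0)
        np.testing.assert_allclose(a.theta, b.theta, atol=1e-12)

    def test_zero_arom_rejected(self):
        with pytest.raises(InvalidParameterError):
            preprocess_epoch(Epoch(theta=np.ones(10), fs=FS), 0.0)


class TestMaxXcorr:
    def test_self_correlation_is_one_at_lag_zero(self):
        x = Epoch(theta=pulse(), fs=FS)
        r = max_xcorr(x, x)
        assert r.sigma == pytest.approx(1.0, abs=1e-12)
        assert r.lag_s == 0.0

    def test_negation_gives_minus_one(self):
        x = pulse()
        lags, sigma = xcorr_normalized(Epoch(x, FS), Epoch(-x, FS))
        assert sigma[lags == 0][0] == pytest.approx(-1.0, abs=1e-12)

    def test_pure_delay_recovered(self):
        x = pulse(center_s=1.0)
        y = pulse(center_s=1.25)
        r = max_xcorr(Epoch(x, FS), Epoch(y, FS))
        assert r.lag_s == pytest.approx(0.25, abs=1.5 / FS)
        assert r.sigma > 0.99

    def test_matches_brute_force_to_1e10(self):
        rng = np.random.default_rng(5)
        a = rng.standard_normal(64)
        b = rng.standard_normal(64)
        lags, sigma = xcorr_normalized(Epoch(a, FS), Epoch(b, FS))
        brute = brute_force_sigma(a, b)
        for m, s in zip(lags, sigma):
            assert abs(s - brute[int(m)]) < 1e-10

    def test_symmetry_and_scale_invariance(self):
        rng = np.random.default_rng(8)
        a, b = rng.standard_normal(50), rng.standard_normal(50)
        r_ab = max_xcorr(Epoch(a, FS), Epoch(b, FS))
        r_ba = max_xcorr(Epoch(b, FS), Epoch(a, FS))
        assert r_ab.sigma == pytest.approx(r_ba.sigma, abs=1e-12)
        r_scaled = max_xcorr(Epoch(3.7 * a, FS), Epoch(0.2 * b, FS))
        assert r_scaled.sigma == pytest.approx(r_ab.sigma, abs=1e-12)

    def test_unequal_lengths_zero_padded(self):
        x = pulse()
        r = max_xcorr(Epoch(x, FS), Epoch(x[: x.size // 2], FS))
        assert -1.0 <= r.sigma <= 1.0

    def test_zero_energy_rejected(self):
        with pytest.raises(UndefinedCorrelationError):
            max_xcorr(Epoch(np.zeros(10), FS), Epoch(np.ones(10), FS))


class TestSessionSimilarity:
    def _trace(self, n_reps=4):
        env = make_activation_profile(n_reps, 4.0, 3.0)
        return therapist_angle(env, arom_deg=60.0)

    def test_identical_traces_perfect_similarity(self):
        th = self._trace()
        results, summary = session_similarity(th, th, n_reps=4)
        assert summary["sigma_mean"] == pytest.approx(1.0, abs=1e-9)
        assert summary["sigma_sd"] == pytest.approx(0.0, abs=1e-9)

    def test_delayed_lowpassed_patient_high_similarity(self):
        th = self._trace()
        # patient: delayed, attenuated, slightly smoothed copy
        d = int(0.3 * FS)
        pt_theta = 0.7 * np.convolve(
            np.roll(th.theta, d), np.ones(5) / 5, mode="same"
        )
        pt_theta[:d] = 0.0
        pt = AngularSignal(fs=FS, theta=pt_theta)
        results, summary = session_similarity(th, pt, n_reps=4)
        assert all(r.sigma > 0.95 for r in results)

    def test_mismatched_spans_rejected(self):
        th = self._trace()
        pt = AngularSignal(fs=FS, theta=th.theta[:-50])
        with pytest.raises(SegmentationError):
            session_similarity(th, pt, n_reps=4)
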