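"""Seedable synthetic inputs: activation envelopes, surrogate sEMG, angles.

The sEMG surrogate is amplitude-modulated band-limited Gaussian noise — the
minimal model under which the threshold-crossing rate grows monotonically
with activation, which is exactly the property the average-threshold-crossing
(ATC) feature exploits. The angle generator maps smoothed activation to a
joint angle and emulates a 12-bit absolute encoder sampled at 80 Hz.
"""

from __future__ import annotations

import numpy as np
from scipy import signal as sps

from .signals import (
    GONIO_FS_HZ,
    ActivationEnvelope,
    AliasingError,
    AngularSignal,
    InvalidParameterError,
    SEMGSignal,
    quantize_angle,
)

#: Default simulation sampling rate for raw sEMG, Hz (the analog chain is
#: band-limited to 400 Hz; 2 kHz resolves the full conditioning band).
SEMG_FS_HZ = 2000.0

#: Default surrogate band, Hz, matching the conditioning chain's passband.
SEMG_BAND_HZ = (30.0, 400.0)

#: Cut-off of the 2nd-order low-pass applied to activation before mapping it
#: to a joint angle, Hz — the bandwidth of voluntary human limb movement.
ANGLE_SMOOTH_HZ = 3.0


def make_activation_profile(
    n_reps: int,
    rep_duration_s: float,
    rest_s: float,
    rise_frac: float = 0.25,
    peak: float = 1.0,
    fs: float = GONIO_FS_HZ,
) -> ActivationEnvelope:
    """Trapezoidal repetition protocol: ``n_reps`` bursts separated by rest.

    Each burst ramps up for ``rise_frac`` of its duration, holds ``peak``,
    then ramps down over the same fraction. Rest segments (including a
    leading and a trailing one) are exactly zero, so total duration is
    ``n_reps*rep_duration_s + (n_reps+1)*rest_s``.
    """
    if n_reps < 1:
        raise InvalidParameterError("n_reps must be >= 1")
    if rep_duration_s <= 0 or rest_s <= 0 or fs <= 0:
        raise InvalidParameterError("durations and fs must be positive")
    if not 0 < rise_frac < 0.5:
        raise InvalidParameterError("rise_frac must lie in (0, 0.5)")
    if not 0 <= peak <= 1:
        raise InvalidParameterError("peak must lie in [0, 1]")

    total_s = n_reps * rep_duration_s + (n_reps + 1) * rest_s
    n = int(round(total_s * fs))
    t = np.arange(n) / fs
    a = np.zeros(n)
    rise_s = rise_frac * rep_duration_s
    for k in range(n_reps):
        onset = rest_s + k * (rep_duration_s + rest_s)
        tau = t - onset
        in_rep = (tau >= 0) & (tau < rep_duration_s)
        shape = np.minimum.reduce([
            tau / rise_s,
            (rep_duration_s - tau) / rise_s,
            np.ones_like(tau),
        ])
        a[in_rep] = peak * np.clip(shape[in_rep], 0.0, 1.0)
    return ActivationEnvelope(t=t, a=a)


def synthesize_semg(
    env: ActivationEnvelope,
    fs: float = SEMG_FS_HZ,
    gain_mv: float = 2.0,
    noise_floor_mv: float = 0.02,
    band: tuple[float, float] = SEMG_BAND_HZ,
    seed: int = 0,
    channel_id: str = "ch0",
) -> SEMGSignal:
    """Amplitude-modulated band-limited Gaussian sEMG surrogate.

    v(t) = (noise_floor_mv + gain_mv * a(t)) * w(t), with w zero-mean,
    unit-variance noise band-passed to ``band``. Electrode-scale defaults:
    20 uV RMS baseline (typical electrode-amplifier noise, i.e. 20 mV after
    the 1000x conditioning gain — the regime a ~30 mV comparator hysteresis
    is sized for) and 2 mV RMS at full activation (raw sEMG spans hundreds
    of uV to tens of mV peak). Deterministic for a fixed seed.
    """
    if gain_mv <= 0:
        raise InvalidParameterError("gain_mv must be positive")
    if noise_floor_mv < 0:
        raise InvalidParameterError("noise_floor_mv must be non-negative")
    lo, hi = band
    if not 0 < lo < hi:
        raise InvalidParameterError("band must satisfy 0 < low < high")
    if fs < 2 * hi:
        raise AliasingError(f"fs={fs} Hz cannot represent content up to {hi} Hz")

    n = int(round(env.duration_s * fs))
    rng = np.random.default_rng(seed)
    w = rng.standard_normal(n)
    sos = sps.butter(4, [lo, hi], btype="bandpass", fs=fs, output="sos")
    w = sps.sosfilt(sos, w)
    # renormalize to unit variance after band-limiting
    std = w.std()
    if std > 0:
        w /= std
    t = np.arange(n) / fs
    a = np.interp(t, env.t, env.a, left=0.0, right=0.0)
    v = (noise_floor_mv + gain_mv * a) * w
    return SEMGSignal(fs=fs, v=v, channel_id=channel_id)


def therapist_angle(
    env: ActivationEnvelope,
    arom_deg: float,
    fs: float = GONIO_FS_HZ,
    quantize: bool = True,
    smooth_hz: float = ANGLE_SMOOTH_HZ,
) -> AngularSignal:
    """Joint angle proportional to smoothed activation, goniometer-style.

    theta = arom_deg * smooth(a) resampled to ``fs``; the smoothing is a
    zero-phase 2nd-order low-pass at ``smooth_hz`` so the angle peak still
    reaches ``arom_deg`` at full activation. With ``quantize`` the samples
    snap to the 12-bit encoder grid (360/4096 deg per count).
    """
    if arom_deg <= 0:
        raise InvalidParameterError("arom_deg must be positive")
    t_out = np.arange(int(round(env.duration_s * fs))) / fs
    a = np.interp(t_out, env.t, env.a, left=0.0, right=0.0)
    if smooth_hz > 0 and smooth_hz < fs / 2:
        sos = sps.butter(2, smooth_hz, btype="lowpass", fs=fs, output="sos")
        a = sps.sosfiltfilt(sos, a)
        peak = a.max()
        src_peak = env.a.max()
        if peak > 0 and src_peak > 0:
            a *= src_peak / peak  # restore the configured peak after smoothing
    theta = arom_deg * np.clip(a, 0.0, 1.0)
    if quantize:
        theta = quantize_angle(theta)
    return AngularSignal(fs=fs, theta=theta, quantized=quantize)
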