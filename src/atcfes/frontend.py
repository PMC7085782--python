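"""Analog front end: conditioning chain model and hysteresis event detector.

The conditioning chain mirrors the acquisition hardware: a first-order
high-pass at 30 Hz cascaded with a second-order (Sallen-Key-style) low-pass
at 400 Hz, with a 1000x in-band gain. Filtering is causal — the hardware
runs in real time, so no zero-phase tricks.

Threshold-crossing (TC) events come from a Schmitt-trigger comparator:
an event fires when the signal rises to the threshold while the detector is
armed; it re-arms only once the signal falls back below threshold minus the
hysteresis width (~30 mV in the hardware), which suppresses spurious
glitches around the threshold.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .signals import AliasingError, InvalidParameterError, SEMGSignal


@dataclass(frozen=True)
class ConditioningConfig:
    """Corner frequencies and gain of the analog conditioning cascade."""

    hp_corner: float = 30.0
    lp_corner: float = 400.0
    gain: float = 1000.0

    def __post_init__(self) -> None:
        if not 0 < self.hp_corner < self.lp_corner:
            raise InvalidParameterError("need 0 < hp_corner < lp_corner")
        if self.gain <= 0:
            raise InvalidParameterError("gain must be positive")

    def sos(self, fs: float) -> np.ndarray:
        """Second-order sections of the digital HP1*LP2 cascade at rate fs."""
        hp = sps.butter(1, self.hp_corner, btype="highpass", fs=fs, output="sos")
        lp = sps.butter(2, self.lp_corner, btype="lowpass", fs=fs, output="sos")
        return np.vstack([hp, lp])

    def response_at(self, f_hz: float, fs: float) -> float:
        """Magnitude of the designed digital cascade at ``f_hz`` (gain included)."""
        w, h = sps.sosfreqz(self.sos(fs), worN=[f_hz], fs=fs)
        return float(self.gain * np.abs(h[0]))


@dataclass(frozen=True)
class EventTrain:
    """Strictly increasing timestamps of threshold-crossing events."""

    times: np.ndarray
    span: tuple[float, float]

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        t0, t1 = self.span
        if times.size and not np.all(np.diff(times) > 0):
            raise InvalidParameterError("event times must be strictly increasing")
        if times.size and (times[0] < t0 or times[-1] > t1):
            raise InvalidParameterError("event times outside span")
        object.__setattr__(self, "times", times)

    def __len__(self) -> int:
        return int(self.times.size)


def condition_signal(raw: SEMGSignal, cfg: ConditioningConfig | None = None) -> SEMGSignal:
    """Apply the conditioning cascade: gain * LP2(HP1(raw)), causal."""
    cfg = cfg or ConditioningConfig()
    if raw.fs < 2 * cfg.lp_corner:
        raise AliasingError(
            f"fs={raw.fs} Hz below twice the low-pass corner {cfg.lp_corner} Hz"
        )
    v = cfg.gain * sps.sosfilt(cfg.sos(raw.fs), raw.v)
    return SEMGSignal(fs=raw.fs, v=v, channel_id=raw.channel_id)


def detect_tc_events(
    sig: SEMGSignal, threshold_mv: float, hysteresis_mv: float = 30.0
) -> EventTrain:
    """Schmitt-trigger event detection on a conditioned sEMG trace.

    The detector starts armed. It emits an event at the first sample whose
    value reaches ``threshold_mv``, then stays disarmed until a sample falls
    to ``threshold_mv - hysteresis_mv`` or below. Only rising crossings
    count; timestamps are the crossing sample's time (no interpolation).
    """
    if hysteresis_mv < 0:
        raise InvalidParameterError("hysteresis_mv must be non-negative")
    v = sig.v
    if not np.all(np.isfinite(v)):
        raise InvalidParameterError("signal contains NaN or Inf")

    trigger = v >= threshold_mv
    rearm = v <= threshold_mv - hysteresis_mv
    trig_idx = np.flatnonzero(trigger)
    rearm_idx = np.flatnonzero(rearm)

    events: list[int] = []
    pos = 0  # next sample index eligible to trigger
    while True:
        k = np.searchsorted(trig_idx, pos)
        if k == len(trig_idx):
            break
        i = trig_idx[k]
        events.append(i)
        j = np.searchsorted(rearm_idx, i + 1)
        if j == len(rearm_idx):
            break
        pos = rearm_idx[j] + 1

    times = np.asarray(events, dtype=float) / sig.fs
    return EventTrain(times=times, span=(0.0, sig.duration_s))
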