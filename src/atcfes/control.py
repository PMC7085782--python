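"""Run-time stimulation controller: ATC matrix, moving median, current LUT.

Every new ATC window shifts a per-channel ring buffer of the four most
recent counts (the "ATC matrix"). The row median of those four values —
a moving median, robust to single-window noise — is rounded to an integer
index into the per-channel FES current lookup table. The table's first two
entries are zero (the noise gateway: baseline-level counts never
stimulate); above the gate it ramps to the calibrated maximal current at
index atc_max. The resulting amplitude parameterizes a charge-balanced
biphasic rectangular pulse whose interphase gap is fixed at 150 us.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .signals import InvalidParameterError

#: Fixed interphase interval of the biphasic pulse, microseconds.
INTERPHASE_US = 150.0

#: Width of the noise gateway: lowest LUT indices forced to zero current.
GATE_LEVELS = 2

#: Session-constant pulse defaults (amplitude is the modulated quantity).
DEFAULT_FREQUENCY_HZ = 25.0
DEFAULT_PHASE_WIDTH_US = 300.0

#: Device-safe bounds for the session constants.
FREQUENCY_BOUNDS_HZ = (1.0, 100.0)
PHASE_WIDTH_BOUNDS_US = (20.0, 1000.0)


class SafetyError(ValueError):
    """A commanded stimulation parameter violates device-safe bounds."""


class InvalidCalibrationError(InvalidParameterError):
    """Calibration values cannot produce a consistent lookup table."""


@dataclass(frozen=True)
class CurrentLUT:
    """Per-channel FES current table: index 0..atc_max -> amplitude (mA)."""

    levels_ma: tuple[tuple[float, ...], ...]  # one tuple per channel

    def __post_init__(self) -> None:
        for ch, levels in enumerate(self.levels_ma):
            if len(levels) < GATE_LEVELS + 1:
                raise InvalidCalibrationError(f"channel {ch}: table too short")
            if any(levels[i] != 0.0 for i in range(GATE_LEVELS)):
                raise InvalidCalibrationError(f"channel {ch}: noise gate not zeroed")
            if any(b < a for a, b in zip(levels, levels[1:])):
                raise InvalidCalibrationError(f"channel {ch}: levels must be non-decreasing")

    @property
    def n_channels(self) -> int:
        return len(self.levels_ma)

    def atc_max(self, ch: int) -> int:
        return len(self.levels_ma[ch]) - 1

    def i_max_ma(self, ch: int) -> float:
        return self.levels_ma[ch][-1]


def build_current_matrix(
    atc_max: int | Sequence[int],
    i_max_ma: float | Sequence[float],
    gate_levels: int = GATE_LEVELS,
) -> CurrentLUT:
    """Linear-ramp LUT: levels[i] = i_max * i / atc_max above the gate.

    Scalar arguments build a single-channel table; sequences build one
    channel per entry. Indices below ``gate_levels`` are forced to zero.
    """
    atc_maxes = [atc_max] if np.isscalar(atc_max) else list(atc_max)
    i_maxes = [i_max_ma] if np.isscalar(i_max_ma) else list(i_max_ma)
    if len(atc_maxes) != len(i_maxes):
        raise InvalidCalibrationError("atc_max and i_max_ma lengths differ")
    channels = []
    for m, imax in zip(atc_maxes, i_maxes):
        m = int(m)
        if m < gate_levels:
            raise InvalidCalibrationError(
                f"atc_max={m} below the {gate_levels}-level noise gate"
            )
        if imax < 0:
            raise InvalidCalibrationError("i_max_ma must be non-negative")
        levels = [0.0 if i < gate_levels else imax * i / m for i in range(m + 1)]
        channels.append(tuple(levels))
    return CurrentLUT(levels_ma=tuple(channels))


@dataclass(frozen=True)
class ControlState:
    """n_channels x 4 ring buffer of the current and three past ATC counts."""

    atc_matrix: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.atc_matrix, dtype=np.int64)
        if m.ndim != 2 or m.shape[1] != 4:
            raise InvalidParameterError("atc_matrix must be n_channels x 4")
        if np.any(m < 0):
            raise InvalidParameterError("ATC counts must be non-negative")
        object.__setattr__(self, "atc_matrix", m)

    @classmethod
    def zeros(cls, n_channels: int) -> "ControlState":
        return cls(atc_matrix=np.zeros((n_channels, 4), dtype=np.int64))

    @property
    def n_channels(self) -> int:
        return int(self.atc_matrix.shape[0])


def update_control(state: ControlState, new_counts: Sequence[int]) -> ControlState:
    """Drop the oldest column, append the new per-channel counts. Pure."""
    counts = np.asarray(new_counts, dtype=np.int64)
    if counts.shape != (state.n_channels,):
        raise InvalidParameterError(
            f"expected {state.n_channels} counts, got shape {counts.shape}"
        )
    if np.any(counts < 0):
        raise InvalidParameterError("ATC counts must be non-negative")
    m = np.column_stack([state.atc_matrix[:, 1:], counts])
    return ControlState(atc_matrix=m)


def median_index(state: ControlState, lut: CurrentLUT) -> np.ndarray:
    """Row median of the 4-wide ATC matrix as LUT indices.

    Median of four is the mean of the middle pair; it is rounded half-up
    (indices are integral) and clamped to [0, atc_max] per channel —
    out-of-calibration counts saturate at the table's top entry.
    """
    med = np.median(state.atc_matrix, axis=1)
    idx = np.floor(med + 0.5).astype(np.int64)
    caps = np.array([lut.atc_max(ch) for ch in range(lut.n_channels)])
    return np.clip(idx, 0, caps)


def lookup_currents(lut: CurrentLUT, indices: Sequence[int]) -> np.ndarray:
    """Amplitude per channel: lut.levels[ch][index[ch]] (mA)."""
    idx = np.asarray(indices, dtype=np.int64)
    if idx.shape != (lut.n_channels,):
        raise InvalidParameterError("one index per channel required")
    return np.array([lut.levels_ma[ch][int(i)] for ch, i in enumerate(idx)])


@dataclass(frozen=True)
class FESCommand:
    """Per-channel biphasic rectangular pulse parameterization.

    Only the amplitude is modulated at run time; frequency and phase width
    are session constants, and the interphase gap is fixed at 150 us.
    """

    amplitudes_ma: tuple[float, ...]
    frequency_hz: float = DEFAULT_FREQUENCY_HZ
    phase_width_us: float = DEFAULT_PHASE_WIDTH_US
    interphase_us: float = INTERPHASE_US
    shape: str = "biphasic-rectangular"

    def __post_init__(self) -> None:
        if any(a < 0 for a in self.amplitudes_ma):
            raise InvalidParameterError("amplitudes must be non-negative")
        if self.interphase_us != INTERPHASE_US:
            raise InvalidParameterError(
                f"interphase interval is fixed at {INTERPHASE_US} us"
            )

    def to_line_protocol(self) -> str:
        """Simplified one-line text form of the stimulator update."""
        amps = ",".join(f"{a:.3f}" for a in self.amplitudes_ma)
        return (f"FES amp_ma=[{amps}] freq_hz={self.frequency_hz:g} "
                f"width_us={self.phase_width_us:g} interphase_us={self.interphase_us:g}")


def build_fes_command(
    amplitudes_ma: Sequence[float],
    frequency_hz: float = DEFAULT_FREQUENCY_HZ,
    phase_width_us: float = DEFAULT_PHASE_WIDTH_US,
    i_max_ma: Sequence[float] | None = None,
) -> FESCommand:
    """Assemble a command, clamping each amplitude to its calibrated limit."""
    if not FREQUENCY_BOUNDS_HZ[0] <= frequency_hz <= FREQUENCY_BOUNDS_HZ[1]:
        raise SafetyError(f"frequency {frequency_hz} Hz outside {FREQUENCY_BOUNDS_HZ}")
    if not PHASE_WIDTH_BOUNDS_US[0] <= phase_width_us <= PHASE_WIDTH_BOUNDS_US[1]:
        raise SafetyError(f"phase width {phase_width_us} us outside {PHASE_WIDTH_BOUNDS_US}")
    amps = [float(a) for a in amplitudes_ma]
    if any(a < 0 for a in amps):
        raise InvalidParameterError("amplitudes must be non-negative")
    if i_max_ma is not None:
        if len(i_max_ma) != len(amps):
            raise InvalidParameterError("one current limit per channel required")
        amps = [min(a, float(m)) for a, m in zip(amps, i_max_ma)]
    return FESCommand(
        amplitudes_ma=tuple(amps),
        frequency_hz=frequency_hz,
        phase_width_us=phase_width_us,
    )


def synthesize_pulse_waveform(
    cmd: FESCommand, fs: float, duration_s: float, channel: int = 0
) -> np.ndarray:
    """Render the commanded pulse train as a sampled current trace (mA).

    Each period holds +amplitude for the phase width, zero for the 150 us
    interphase, -amplitude for the phase width, then zero until the next
    pulse. Verification aid; requires >= 10 samples per phase.
    """
    width_s = cmd.phase_width_us * 1e-6
    inter_s = cmd.interphase_us * 1e-6
    if fs < 10.0 / width_s:
        raise InvalidParameterError(
            f"fs={fs} Hz cannot resolve a {cmd.phase_width_us} us phase with >= 10 samples"
        )
    period_s = 1.0 / cmd.frequency_hz
    if 2 * width_s + inter_s > period_s:
        raise SafetyError("pulse does not fit in one stimulation period")
    amp = cmd.amplitudes_ma[channel]
    n = int(round(duration_s * fs))
    t = np.arange(n) / fs
    phase_t = np.mod(t, period_s)
    out = np.zeros(n)
    out[phase_t < width_s] = amp
    neg = (phase_t >= width_s + inter_s) & (phase_t < 2 * width_s + inter_s)
    out[neg] = -amp
    return out
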