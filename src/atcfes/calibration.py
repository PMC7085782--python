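"""Per-subject, per-channel calibration of the acquisition and stimulation sides.

Four steps, run before a session:

1. Threshold setting — with the limb at rest, sweep the comparator threshold
   downward from a high start value until the rest signal first produces
   threshold-crossing activity (the baseline); the working threshold is set
   30 mV above that baseline, mirroring the comparator's hysteresis width.
2. Maximal ATC — the subject repeats the movement (at least four times);
   the maximal ATC is the median of the per-repetition maxima.
3. AROM evaluation (optional) — the absolute range of motion is the span
   max(theta) - min(theta) of the recorded joint angle.
4. Current limitation — the maximal stimulation current is 110% of the
   current that produces a 30% AROM change in the stimulated limb.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .atc import ATC_WINDOW_S, ATCSeries
from .frontend import detect_tc_events
from .plant import PlantModel
from .signals import AngularSignal, InvalidParameterError, SEMGSignal

#: Margin added above the detected rest baseline, mV (the comparator's
#: hysteresis width).
THRESHOLD_MARGIN_MV = 30.0

#: Default hardware ceiling for stimulation amplitude, mA (8-channel
#: clinical stimulator class bound).
STIMULATOR_MAX_MA = 130.0


class CalibrationFailureError(RuntimeError):
    """A calibration step could not find a valid operating point."""


class InsufficientRepetitionsError(InvalidParameterError):
    """Fewer movement repetitions than the calibration protocol requires."""


class ZeroAROMError(CalibrationFailureError):
    """The angular recording shows no motion."""


@dataclass(frozen=True)
class CalibrationProfile:
    """Everything the controller needs about one subject pair.

    Per-channel sequences are indexed by channel; ``arom_deg`` is optional
    because the goniometers are optional hardware.
    """

    threshold_mv: tuple[float, ...]
    atc_max: tuple[int, ...]
    i_max_ma: tuple[float, ...]
    arom_deg: float | None = None

    def __post_init__(self) -> None:
        if not (len(self.threshold_mv) == len(self.atc_max) == len(self.i_max_ma)):
            raise InvalidParameterError("per-channel fields must have equal length")
        if any(t <= 0 for t in self.threshold_mv):
            raise InvalidParameterError("threshold_mv must be positive")
        if any(m < 1 for m in self.atc_max):
            raise InvalidParameterError("atc_max must be >= 1")
        if any(i < 0 for i in self.i_max_ma):
            raise InvalidParameterError("i_max_ma must be non-negative")
        if self.arom_deg is not None and self.arom_deg <= 0:
            raise InvalidParameterError("arom_deg must be positive when present")

    @property
    def n_channels(self) -> int:
        return len(self.threshold_mv)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "CalibrationProfile":
        d = json.loads(Path(path).read_text())
        return cls(
            threshold_mv=tuple(d["threshold_mv"]),
            atc_max=tuple(int(x) for x in d["atc_max"]),
            i_max_ma=tuple(d["i_max_ma"]),
            arom_deg=d.get("arom_deg"),
        )


def detect_rest_baseline(
    rest: SEMGSignal,
    v_start_mv: float = 200.0,
    v_step_mv: float = 5.0,
    rate_criterion: float = 1.0,
    window_s: float = ATC_WINDOW_S,
    hysteresis_mv: float = THRESHOLD_MARGIN_MV,
) -> float:
    """Step-down baseline search on a rest recording.

    Starting at ``v_start_mv`` and descending in ``v_step_mv`` steps,
    returns the first (largest) tested level at which the rest signal's TC
    rate reaches ``rate_criterion`` events per ATC window — the top of the
    baseline noise. Raises ``CalibrationFailureError`` if no tested level
    above zero meets the criterion (e.g., an identically zero recording).
    """
    if v_step_mv <= 0:
        raise InvalidParameterError("v_step_mv must be positive")
    if rate_criterion <= 0:
        raise InvalidParameterError("rate_criterion must be positive")
    n_windows = max(rest.duration_s / window_s, 1e-12)
    level = v_start_mv
    while level > 0:
        events = detect_tc_events(rest, level, hysteresis_mv)
        if len(events) / n_windows >= rate_criterion:
            return level
        level -= v_step_mv
    raise CalibrationFailureError(
        "rest signal never reached the TC-rate criterion; no baseline found"
    )


def calibrate_threshold(
    rest: SEMGSignal,
    v_start_mv: float = 200.0,
    v_step_mv: float = 5.0,
    rate_criterion: float = 1.0,
    window_s: float = ATC_WINDOW_S,
    hysteresis_mv: float = THRESHOLD_MARGIN_MV,
) -> float:
    """Working comparator threshold: detected rest baseline + 30 mV."""
    baseline = detect_rest_baseline(
        rest, v_start_mv, v_step_mv, rate_criterion, window_s, hysteresis_mv
    )
    return baseline + THRESHOLD_MARGIN_MV


def calibrate_atc_max(rep_series: Sequence[ATCSeries | np.ndarray]) -> int:
    """Median of per-repetition maximal ATC counts, rounded to an integer.

    Requires at least four repetitions. An even count's median (mean of the
    middle pair) is rounded half-up, since ATC indices are integral.
    """
    if len(rep_series) < 4:
        raise InsufficientRepetitionsError(
            f"need at least 4 repetitions, got {len(rep_series)}"
        )
    maxima = []
    for s in rep_series:
        counts = s.counts if isinstance(s, ATCSeries) else np.asarray(s)
        if counts.size == 0:
            raise InvalidParameterError("empty repetition series")
        maxima.append(int(counts.max()))
    med = float(np.median(maxima))
    return int(np.floor(med + 0.5))


def evaluate_arom(angle: AngularSignal) -> float:
    """Absolute range of motion: max(theta) - min(theta) over the recording."""
    theta = angle.theta
    if theta.size == 0:
        raise InvalidParameterError("empty angular signal")
    arom = float(theta.max() - theta.min())
    if arom == 0.0:
        raise ZeroAROMError("constant angular signal; no motion recorded")
    return arom


def calibrate_current_limit(
    plant: PlantModel,
    arom_deg: float,
    i_grid_ma: Sequence[float] | None = None,
    i_ceiling_ma: float = STIMULATOR_MAX_MA,
) -> float:
    """Find 110% of the smallest grid current causing a 30% AROM change.

    Sweeps an ascending current grid (default 0.5 mA steps up to the
    stimulator ceiling), queries the plant's steady-state angle at each
    level and takes the first current whose angle change from rest reaches
    0.30 * arom_deg. The returned limit is 1.1x that current, clamped to
    the stimulator ceiling.
    """
    if arom_deg <= 0:
        raise InvalidParameterError("arom_deg must be positive")
    if i_grid_ma is None:
        i_grid_ma = np.arange(0.0, i_ceiling_ma + 1e-9, 0.5)
    grid = np.asarray(i_grid_ma, dtype=float)
    if grid.size and np.any(np.diff(grid) <= 0):
        raise InvalidParameterError("i_grid_ma must be strictly ascending")
    target = 0.30 * arom_deg
    rest_angle = plant.steady_state_angle(0.0)
    for i_ma in grid:
        delta = plant.steady_state_angle(float(i_ma)) - rest_angle
        if delta >= target - 1e-9:
            return min(1.1 * float(i_ma), i_ceiling_ma)
    raise CalibrationFailureError(
        "no grid current produced a 30% AROM change in the plant"
    )
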