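"""Simulated stimulated limb: recruitment curve + first-order lag + delay.

A deliberately simple test double for the patient. Stimulation amplitude I
maps through a monotone recruitment curve r(I) in [0, 1] to a target
activation; activation follows a first-order lag da/dt = (r(I) - a)/tau and
the joint angle is theta = arom * a, emitted after a pure electromechanical
delay. The recruitment ceiling defaults below 1.0: surface stimulation of a
limb typically evokes a smaller peak excursion than the voluntary movement.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field

import numpy as np

from .signals import InvalidParameterError


@dataclass(frozen=True)
class RecruitmentCurve:
    """Piecewise-linear recruitment: dead zone, linear rise, saturation.

    r(I) = 0 for I <= threshold_ma, then rises linearly with
    ``slope_per_ma`` and saturates at ``ceiling`` (<= 1).
    """

    threshold_ma: float = 2.0
    slope_per_ma: float = 0.08
    ceiling: float = 0.85

    def __post_init__(self) -> None:
        if self.threshold_ma < 0 or self.slope_per_ma <= 0 or not 0 < self.ceiling <= 1:
            raise InvalidParameterError("invalid recruitment parameters")

    def __call__(self, amplitude_ma: float | np.ndarray) -> float | np.ndarray:
        i = np.asarray(amplitude_ma, dtype=float)
        r = np.clip((i - self.threshold_ma) * self.slope_per_ma, 0.0, self.ceiling)
        return float(r) if np.isscalar(amplitude_ma) else r


@dataclass
class PlantModel:
    """First-order limb model with electromechanical delay.

    Parameters
    ----------
    recruitment : callable mA -> activation in [0, 1], non-decreasing.
    tau_s : activation time constant (s).
    delay_s : pure input-output delay (s).
    arom_deg : joint angle at full activation (deg).
    """

    recruitment: RecruitmentCurve = field(default_factory=RecruitmentCurve)
    tau_s: float = 0.25
    delay_s: float = 0.15
    arom_deg: float = 60.0
    state: float = 0.0
    _dl_t: list = field(default_factory=list, repr=False)
    _dl_a: list = field(default_factory=list, repr=False)
    _t: float = field(default=0.0, repr=False)

    def __post_init__(self) -> None:
        if self.tau_s <= 0 or self.delay_s < 0 or self.arom_deg <= 0:
            raise InvalidParameterError("invalid plant parameters")

    def reset(self) -> None:
        self.state = 0.0
        self._t = 0.0
        self._dl_t.clear()
        self._dl_a.clear()

    def steady_state_angle(self, amplitude_ma: float) -> float:
        """Closed-form fixed point of the lag: arom * r(I)."""
        if amplitude_ma < 0:
            raise InvalidParameterError("amplitude must be non-negative")
        return self.arom_deg * float(self.recruitment(amplitude_ma))

    def step(self, amplitude_ma: float, dt_s: float) -> float:
        """Advance one step under constant amplitude; return the delayed angle.

        Exact discretization of the first-order lag over dt (the input is
        held constant within the step), plus delay-line bookkeeping.
        """
        if amplitude_ma < 0:
            raise InvalidParameterError("amplitude must be non-negative")
        if not 0 < dt_s < self.tau_s:
            raise InvalidParameterError("need 0 < dt_s < tau_s")
        target = float(self.recruitment(amplitude_ma))
        decay = np.exp(-dt_s / self.tau_s)
        self.state = target + (self.state - target) * decay
        self._t += dt_s
        self._dl_t.append(self._t)
        self._dl_a.append(self.state)
        # prune entries no future query (time only moves forward) can reach
        cutoff = self._t - self.delay_s
        while len(self._dl_t) > 1 and self._dl_t[1] <= cutoff:
            self._dl_t.pop(0)
            self._dl_a.pop(0)
        return self.angle_at(self._t)

    def angle_at(self, t_s: float) -> float:
        """Angle arom * a(t - delay); zero before the delay has elapsed."""
        t_query = t_s - self.delay_s
        if t_query <= 0 or not self._dl_t:
            return 0.0
        k = bisect.bisect_right(self._dl_t, t_query) - 1
        if k < 0:
            return 0.0
        return self.arom_deg * self._dl_a[k]

    def simulate(self, amplitudes_ma: np.ndarray, dt_s: float) -> np.ndarray:
        """Run a full amplitude sequence; returns the delayed angle per step."""
        return np.array([self.step(float(a), dt_s) for a in amplitudes_ma])


def linear_plant(gain_deg_per_ma: float, arom_deg: float, tau_s: float = 0.25,
                 delay_s: float = 0.0) -> PlantModel:
    """Plant whose steady-state angle is exactly gain * I (up to full AROM).

    Convenience for calibration checks against a known analytic slope.
    """
    rec = RecruitmentCurve(threshold_ma=0.0,
                           slope_per_ma=gain_deg_per_ma / arom_deg,
                           ceiling=1.0)
    return PlantModel(recruitment=rec, tau_s=tau_s, delay_s=delay_s,
                      arom_deg=arom_deg)
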