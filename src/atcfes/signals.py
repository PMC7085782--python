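"""Core signal containers shared across the toolkit.

All signals live on uniform time grids. Units are explicit in field names:
millivolts for sEMG (amplifier-output scale), degrees for joint angles,
seconds for time, milliamperes for stimulation current.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

#: Quantization step of the 12-bit electro-goniometer encoder, in degrees.
GONIO_STEP_DEG = 360.0 / 4096.0

#: Default goniometer sampling rate, Hz.
GONIO_FS_HZ = 80.0


class InvalidParameterError(ValueError):
    """A constructor or operation parameter violates its contract."""


class AliasingError(InvalidParameterError):
    """Sampling rate too low for the requested spectral content."""


@dataclass(frozen=True)
class ActivationEnvelope:
    """Dimensionless muscle-activation drive in [0, 1] on a uniform grid.

    Stands in for the voluntary effort of the subject whose sEMG drives the
    controller; the generator modulates sEMG amplitude with it.
    """

    t: np.ndarray
    a: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.t, dtype=float)
        a = np.asarray(self.a, dtype=float)
        if t.shape != a.shape or t.ndim != 1:
            raise InvalidParameterError("t and a must be 1-D arrays of equal length")
        if t.size >= 2 and not np.all(np.diff(t) > 0):
            raise InvalidParameterError("t must be strictly increasing")
        if a.size and (np.nanmin(a) < -1e-12 or np.nanmax(a) > 1 + 1e-12):
            raise InvalidParameterError("activation must lie in [0, 1]")
        object.__setattr__(self, "t", t)
        object.__setattr__(self, "a", np.clip(a, 0.0, 1.0))

    @property
    def fs(self) -> float:
        return 1.0 / (self.t[1] - self.t[0])

    @property
    def duration_s(self) -> float:
        return self.t.size / self.fs


@dataclass(frozen=True)
class SEMGSignal:
    """A sampled sEMG trace in millivolts.

    The same container holds electrode-scale raw signals and the
    amplifier-conditioned signal (the units stay mV; only the magnitude
    changes by the conditioning gain).
    """

    fs: float
    v: np.ndarray
    channel_id: str = "ch0"

    def __post_init__(self) -> None:
        v = np.asarray(self.v, dtype=float)
        if self.fs <= 0:
            raise InvalidParameterError("fs must be positive")
        if v.ndim != 1:
            raise InvalidParameterError("v must be a 1-D array")
        if not np.all(np.isfinite(v)):
            raise InvalidParameterError("signal contains non-finite values")
        object.__setattr__(self, "v", v)

    @property
    def t(self) -> np.ndarray:
        return np.arange(self.v.size) / self.fs

    @property
    def duration_s(self) -> float:
        return self.v.size / self.fs


@dataclass(frozen=True)
class AngularSignal:
    """A joint-angle trace in degrees, by default on the goniometer grid.

    When ``quantized`` every sample is an integer multiple of the 12-bit
    encoder step (360/4096 deg).
    """

    fs: float
    theta: np.ndarray
    quantized: bool = False

    def __post_init__(self) -> None:
        theta = np.asarray(self.theta, dtype=float)
        if self.fs <= 0:
            raise InvalidParameterError("fs must be positive")
        if theta.ndim != 1:
            raise InvalidParameterError("theta must be a 1-D array")
        if self.quantized:
            resid = np.abs(theta / GONIO_STEP_DEG - np.round(theta / GONIO_STEP_DEG))
            if theta.size and np.max(resid) > 1e-6:
                raise InvalidParameterError(
                    "quantized flag set but samples are off the 12-bit grid"
                )
        object.__setattr__(self, "theta", theta)

    @property
    def t(self) -> np.ndarray:
        return np.arange(self.theta.size) / self.fs

    @property
    def duration_s(self) -> float:
        return self.theta.size / self.fs


def quantize_angle(theta_deg: np.ndarray, step_deg: float = GONIO_STEP_DEG) -> np.ndarray:
    """Round angle samples to the encoder grid (nearest multiple of the step)."""
    return np.round(np.asarray(theta_deg, dtype=float) / step_deg) * step_deg


# ---------------------------------------------------------------------------
# CSV + JSON-sidecar serialization: columns `t_s, value`, metadata alongside.


def write_signal_csv(path: str | Path, t_s: np.ndarray, value: np.ndarray,
                     meta: dict) -> None:
    """Write a `t_s, value` CSV with a `<name>.meta.json` sidecar."""
    path = Path(path)
    pd.DataFrame({"t_s": t_s, "value": value}).to_csv(path, index=False)
    path.with_suffix(path.suffix + ".meta.json").write_text(
        json.dumps(meta, indent=2, sort_keys=True)
    )


def read_signal_csv(path: str | Path) -> tuple[np.ndarray, np.ndarray, dict]:
    """Read a `t_s, value` CSV and its JSON sidecar (empty dict if absent)."""
    path = Path(path)
    df = pd.read_csv(path)
    if not {"t_s", "value"} <= set(df.columns):
        raise InvalidParameterError(f"{path}: expected columns t_s, value")
    sidecar = path.with_suffix(path.suffix + ".meta.json")
    meta = json.loads(sidecar.read_text()) if sidecar.exists() else {}
    return df["t_s"].to_numpy(), df["value"].to_numpy(), meta


def write_semg_csv(path: str | Path, sig: SEMGSignal) -> None:
    write_signal_csv(path, sig.t, sig.v,
                     {"fs": sig.fs, "units": "mV", "channel": sig.channel_id})


def read_semg_csv(path: str | Path) -> SEMGSignal:
    t, v, meta = read_signal_csv(path)
    fs = float(meta.get("fs", 1.0 / (t[1] - t[0])))
    return SEMGSignal(fs=fs, v=v, channel_id=str(meta.get("channel", "ch0")))


def write_angle_csv(path: str | Path, sig: AngularSignal) -> None:
    write_signal_csv(path, sig.t, sig.theta,
                     {"fs": sig.fs, "units": "deg", "quantized": sig.quantized})


def read_angle_csv(path: str | Path) -> AngularSignal:
    t, theta, meta = read_signal_csv(path)
    fs = float(meta.get("fs", 1.0 / (t[1] - t[0])))
    return AngularSignal(fs=fs, theta=theta, quantized=bool(meta.get("quantized", False)))
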