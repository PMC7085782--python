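"""Closed-loop simulated therapy session: calibrate -> stimulate -> evaluate.

Runs the full event-driven pipeline on a virtual clock, one ATC window at a
time: synthetic sEMG -> conditioning -> threshold-crossing events -> windowed
ATC counts -> ATC-matrix update -> moving row-median -> current lookup ->
stimulation command -> simulated limb. Command timestamps are the window end
plus a fixed processing delay (10 ms by default), so the modeled per-window
latency is window + processing = 140 ms with the defaults.

Everything is deterministic for a fixed master seed; per-channel generator
seeds are derived from it with a counter scheme.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import synth
from .atc import ATC_WINDOW_S, count_atc, stream_atc
from .calibration import (
    CalibrationProfile,
    calibrate_atc_max,
    calibrate_current_limit,
    calibrate_threshold,
    evaluate_arom,
)
from .control import (
    DEFAULT_FREQUENCY_HZ,
    DEFAULT_PHASE_WIDTH_US,
    ControlState,
    CurrentLUT,
    build_current_matrix,
    build_fes_command,
    lookup_currents,
    median_index,
    update_control,
)
from .frontend import ConditioningConfig, condition_signal, detect_tc_events
from .plant import PlantModel, RecruitmentCurve
from .signals import (
    GONIO_FS_HZ,
    AngularSignal,
    InvalidParameterError,
    quantize_angle,
)


class ConfigError(InvalidParameterError):
    """Session configuration violates its contract."""


class ParseError(RuntimeError):
    """A session log on disk is malformed."""


@dataclass
class SessionConfig:
    """Parameters of one simulated therapist-patient session.

    The four-channel bound mirrors the acquisition board; ``window_s`` is
    the ATC observation window and ``processing_delay_s`` the modeled
    controller processing time per window.
    """

    n_channels: int = 1
    window_s: float = ATC_WINDOW_S
    seed: int = 0
    processing_delay_s: float = 0.010
    # repetition protocol of the voluntary movement
    n_reps: int = 12
    rep_duration_s: float = 4.0
    rest_s: float = 3.0
    peak_activation: float = 1.0
    duration_s: float | None = None  # override: truncate/extend to a fixed span
    # generator block
    semg_fs: float = synth.SEMG_FS_HZ
    gain_mv: float = 2.0
    noise_floor_mv: float = 0.02
    arom_deg: float = 60.0
    # controller block
    frequency_hz: float = DEFAULT_FREQUENCY_HZ
    phase_width_us: float = DEFAULT_PHASE_WIDTH_US
    # plant block
    plant_tau_s: float = 0.25
    plant_delay_s: float = 0.15
    recruitment_threshold_ma: float = 2.0
    recruitment_slope_per_ma: float = 0.08
    recruitment_ceiling: float = 0.85
    # calibration block
    v_start_mv: float = 200.0
    v_step_mv: float = 5.0
    rate_criterion: float = 1.0

    def __post_init__(self) -> None:
        if not 1 <= self.n_channels <= 4:
            raise ConfigError("n_channels must be between 1 and 4")
        if self.window_s <= 0:
            raise ConfigError("window_s must be positive")
        if self.processing_delay_s < 0:
            raise ConfigError("processing_delay_s must be non-negative")
        if self.n_reps < 1:
            raise ConfigError("n_reps must be >= 1")

    def channel_seed(self, channel: int, stream: int = 0) -> int:
        """Derived seed: master * 10007 + 101*stream + channel, mod 2^31."""
        return (self.seed * 10007 + 101 * stream + channel) % (2**31 - 1)

    def make_plant(self) -> PlantModel:
        return PlantModel(
            recruitment=RecruitmentCurve(
                threshold_ma=self.recruitment_threshold_ma,
                slope_per_ma=self.recruitment_slope_per_ma,
                ceiling=self.recruitment_ceiling,
            ),
            tau_s=self.plant_tau_s,
            delay_s=self.plant_delay_s,
            arom_deg=self.arom_deg,
        )

    @classmethod
    def from_dict(cls, d: dict) -> "SessionConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SessionConfig":
        import yaml

        d = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(d, dict):
            raise ConfigError(f"{path}: expected a mapping at top level")
        return cls.from_dict(d)


@dataclass
class SessionLog:
    """Per-window controller records plus the session's angle traces."""

    records: pd.DataFrame  # one row per ATC window
    therapist_angle: AngularSignal
    patient_angle: AngularSignal
    profile: CalibrationProfile
    config: SessionConfig

    @property
    def n_windows(self) -> int:
        return int(len(self.records))


def _activation(cfg: SessionConfig):
    env = synth.make_activation_profile(
        n_reps=cfg.n_reps,
        rep_duration_s=cfg.rep_duration_s,
        rest_s=cfg.rest_s,
        peak=cfg.peak_activation,
        fs=GONIO_FS_HZ,
    )
    if cfg.duration_s is None:
        return env
    n = int(round(cfg.duration_s * GONIO_FS_HZ))
    t = np.arange(n) / GONIO_FS_HZ
    a = np.interp(t, env.t, env.a, left=0.0, right=0.0)
    return type(env)(t=t, a=a)


def auto_calibrate(cfg: SessionConfig) -> CalibrationProfile:
    """Run the four calibration steps on synthetic calibration recordings."""
    cond = ConditioningConfig()
    thresholds, atc_maxes = [], []
    # rest recording for the threshold step (activation = 0)
    rest_env = synth.make_activation_profile(1, 1.0, 2.0, peak=1.0, fs=GONIO_FS_HZ)
    zero_env = type(rest_env)(t=rest_env.t, a=np.zeros_like(rest_env.a))
    # calibration movement: >= 4 repetitions of the session movement
    cal_env = synth.make_activation_profile(
        4, cfg.rep_duration_s, cfg.rest_s, peak=cfg.peak_activation, fs=GONIO_FS_HZ
    )
    for ch in range(cfg.n_channels):
        rest_raw = synth.synthesize_semg(
            zero_env, fs=cfg.semg_fs, gain_mv=cfg.gain_mv,
            noise_floor_mv=cfg.noise_floor_mv,
            seed=cfg.channel_seed(ch, stream=1), channel_id=f"ch{ch}",
        )
        rest_cond = condition_signal(rest_raw, cond)
        thr = calibrate_threshold(
            rest_cond, cfg.v_start_mv, cfg.v_step_mv, cfg.rate_criterion,
            window_s=cfg.window_s,
        )
        thresholds.append(thr)

        cal_raw = synth.synthesize_semg(
            cal_env, fs=cfg.semg_fs, gain_mv=cfg.gain_mv,
            noise_floor_mv=cfg.noise_floor_mv,
            seed=cfg.channel_seed(ch, stream=2), channel_id=f"ch{ch}",
        )
        cal_cond = condition_signal(cal_raw, cond)
        events = detect_tc_events(cal_cond, thr)
        # split the calibration stream into one ATC series per repetition
        rep_span = cfg.rep_duration_s + cfg.rest_s
        reps = []
        for k in range(4):
            t0 = cfg.rest_s + k * rep_span - 0.5
            t1 = t0 + rep_span
            reps.append(count_atc(events, cfg.window_s, max(t0, 0.0), t1))
        atc_maxes.append(calibrate_atc_max(reps))

    th_angle = synth.therapist_angle(cal_env, arom_deg=cfg.arom_deg)
    arom = evaluate_arom(th_angle)
    plant = cfg.make_plant()
    i_max = calibrate_current_limit(plant, arom)
    return CalibrationProfile(
        threshold_mv=tuple(thresholds),
        atc_max=tuple(atc_maxes),
        i_max_ma=tuple([i_max] * cfg.n_channels),
        arom_deg=arom,
    )


def run_session(
    cfg: SessionConfig, profile: CalibrationProfile | None = None
) -> SessionLog:
    """Execute one closed-loop session on the virtual clock.

    Without a profile, auto-calibration runs first. Returns one record per
    ATC window (timestamps, per-channel counts, median indices, commanded
    amplitudes) plus the therapist and simulated-patient angle traces at
    the goniometer rate.
    """
    if profile is None:
        profile = auto_calibrate(cfg)
    if profile.n_channels != cfg.n_channels:
        raise ConfigError("profile channel count does not match the session")

    env = _activation(cfg)
    duration = env.duration_s
    cond = ConditioningConfig()

    # therapist side: sEMG per channel -> conditioned -> events -> ATC stream
    trains = []
    for ch in range(cfg.n_channels):
        raw = synth.synthesize_semg(
            env, fs=cfg.semg_fs, gain_mv=cfg.gain_mv,
            noise_floor_mv=cfg.noise_floor_mv,
            seed=cfg.channel_seed(ch, stream=0), channel_id=f"ch{ch}",
        )
        conditioned = condition_signal(raw, cond)
        trains.append(detect_tc_events(conditioned, profile.threshold_mv[ch]))
    series = stream_atc(trains, cfg.window_s)

    lut = build_current_matrix(list(profile.atc_max), list(profile.i_max_ma))
    state = ControlState.zeros(cfg.n_channels)
    plant = cfg.make_plant()
    plant.reset()

    gonio_dt = 1.0 / GONIO_FS_HZ
    n_windows = series.n_windows
    pt_theta: list[float] = []
    rows = []
    plant_t = 0.0
    amp_now = 0.0  # zero-order-hold amplitude driving the plant (channel 0)
    for k in range(n_windows):
        t_cmd = (k + 1) * cfg.window_s + cfg.processing_delay_s
        state = update_control(state, series.counts[k])
        idx = median_index(state, lut)
        amps = lookup_currents(lut, idx)
        cmd = build_fes_command(
            amps, cfg.frequency_hz, cfg.phase_width_us, list(profile.i_max_ma)
        )
        rows.append(
            {
                "window_index": k,
                "t_s": k * cfg.window_s,
                "t_command_s": t_cmd,
                **{f"atc_ch{c}": int(series.counts[k, c]) for c in range(cfg.n_channels)},
                **{f"median_ch{c}": int(idx[c]) for c in range(cfg.n_channels)},
                **{f"amp_ma_ch{c}": cmd.amplitudes_ma[c] for c in range(cfg.n_channels)},
            }
        )
        # advance the plant to this command's activation time under the
        # previously commanded amplitude, then switch to the new one
        while plant_t + gonio_dt <= t_cmd + 1e-12:
            pt_theta.append(plant.step(amp_now, gonio_dt))
            plant_t += gonio_dt
        amp_now = float(cmd.amplitudes_ma[0])
    while plant_t + gonio_dt <= duration + 1e-12:
        pt_theta.append(plant.step(amp_now, gonio_dt))
        plant_t += gonio_dt

    th_angle = synth.therapist_angle(env, arom_deg=cfg.arom_deg)
    n = min(len(pt_theta), th_angle.theta.size)
    patient = AngularSignal(
        fs=GONIO_FS_HZ, theta=quantize_angle(np.asarray(pt_theta[:n])), quantized=True
    )
    therapist = AngularSignal(
        fs=GONIO_FS_HZ, theta=th_angle.theta[:n], quantized=th_angle.quantized
    )
    return SessionLog(
        records=pd.DataFrame(rows),
        therapist_angle=therapist,
        patient_angle=patient,
        profile=profile,
        config=cfg,
    )


# ---------------------------------------------------------------------------
# Persistence: CSV records + JSON sidecar + angle CSVs, round-trippable.


def write_session(log: SessionLog, out_dir: str | Path) -> Path:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log.records.to_csv(out / "session_log.csv", index=False)
    pd.DataFrame({"t_s": log.therapist_angle.t, "value": log.therapist_angle.theta}
                 ).to_csv(out / "therapist_angle.csv", index=False)
    pd.DataFrame({"t_s": log.patient_angle.t, "value": log.patient_angle.theta}
                 ).to_csv(out / "patient_angle.csv", index=False)
    log.profile.to_json(out / "calibration_profile.json")
    (out / "session_meta.json").write_text(
        json.dumps(
            {
                "config": asdict(log.config),
                "angle_fs": log.therapist_angle.fs,
                "patient_quantized": log.patient_angle.quantized,
            },
            indent=2,
        )
    )
    return out


def read_session(out_dir: str | Path) -> SessionLog:
    out = Path(out_dir)
    try:
        meta = json.loads((out / "session_meta.json").read_text())
        records = pd.read_csv(out / "session_log.csv")
        th = pd.read_csv(out / "therapist_angle.csv")
        pt = pd.read_csv(out / "patient_angle.csv")
        profile = CalibrationProfile.from_json(out / "calibration_profile.json")
    except (OSError, json.JSONDecodeError, pd.errors.ParserError) as exc:
        raise ParseError(f"cannot read session from {out}: {exc}") from exc
    for name, df, cols in (
        ("session_log.csv", records, {"window_index", "t_s", "t_command_s"}),
        ("therapist_angle.csv", th, {"t_s", "value"}),
        ("patient_angle.csv", pt, {"t_s", "value"}),
    ):
        if not cols <= set(df.columns):
            raise ParseError(f"{name}: missing columns {sorted(cols - set(df.columns))}")
    cfg = SessionConfig.from_dict(meta["config"])
    fs = float(meta.get("angle_fs", GONIO_FS_HZ))
    return SessionLog(
        records=records,
        therapist_angle=AngularSignal(fs=fs, theta=th["value"].to_numpy()),
        patient_angle=AngularSignal(
            fs=fs, theta=pt["value"].to_numpy(),
            quantized=bool(meta.get("patient_quantized", False)),
        ),
        profile=profile,
        config=cfg,
    )
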