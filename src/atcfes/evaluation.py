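"""Movement-similarity evaluation between voluntary and stimulated limbs.

The angular traces of the two limbs are segmented into per-repetition
epochs, baseline-corrected (the limbs may start from different positions),
normalized to each subject's AROM, and compared with the maximum over lags
of the autocorrelation-normalized cross-correlation coefficient

    sigma = max_m  sum_k th(k) pt(k+m) / sqrt(sig_thth(0) * sig_ptpt(0))

which is bounded in [-1, 1]: 1 for a perfect (possibly time-shifted) match,
-1 for exactly opposite signals.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .calibration import CalibrationProfile
from .signals import AngularSignal, InvalidParameterError


class SegmentationError(RuntimeError):
    """The trace does not contain the expected number of movement bursts."""


class UndefinedCorrelationError(ValueError):
    """An epoch has zero energy; the normalized coefficient is undefined."""


@dataclass(frozen=True)
class Epoch:
    """One repetition's angle samples on a uniform grid."""

    theta: np.ndarray
    fs: float
    rep_index: int = 0

    def __post_init__(self) -> None:
        theta = np.asarray(self.theta, dtype=float)
        if theta.ndim != 1 or theta.size == 0:
            raise InvalidParameterError("epoch must be a non-empty 1-D array")
        object.__setattr__(self, "theta", theta)


@dataclass(frozen=True)
class SimilarityResult:
    """Maximum normalized cross-correlation and the lag where it occurs."""

    sigma: float
    lag_s: float
    rep_index: int = 0

    def __post_init__(self) -> None:
        if not -1.0 - 1e-9 <= self.sigma <= 1.0 + 1e-9:
            raise InvalidParameterError("sigma must lie in [-1, 1]")


def _find_bursts(theta: np.ndarray, onset_frac: float) -> list[tuple[int, int]]:
    """Contiguous runs where |theta - rest| exceeds onset_frac of the range."""
    rest = np.median(theta)
    span = theta.max() - theta.min()
    if span <= 0:
        return []
    mask = np.abs(theta - rest) > onset_frac * span
    edges = np.diff(mask.astype(int))
    starts = list(np.flatnonzero(edges == 1) + 1)
    ends = list(np.flatnonzero(edges == -1) + 1)
    if mask[0]:
        starts.insert(0, 0)
    if mask[-1]:
        ends.append(len(mask))
    return list(zip(starts, ends))


def segment_bounds(
    angle: AngularSignal,
    n_reps: int,
    onset_frac: float = 0.1,
    guard_s: float = 0.5,
) -> list[tuple[int, int]]:
    """Sample index windows [lo, hi) of the ``n_reps`` movement bursts.

    Bursts are runs where the deviation from the rest level exceeds
    ``onset_frac`` of the trace's total range; each window is the burst
    padded by ``guard_s`` on both sides (clipped to the trace and to the
    midpoint between neighbouring bursts, so windows never overlap). When
    more bursts than ``n_reps`` are detected the ``n_reps`` longest are
    kept, in temporal order.
    """
    if n_reps < 1:
        raise InvalidParameterError("n_reps must be >= 1")
    theta = angle.theta
    bursts = _find_bursts(theta, onset_frac)
    # drop glitch-scale runs (shorter than 100 ms)
    min_len = max(1, int(round(0.1 * angle.fs)))
    bursts = [(s, e) for s, e in bursts if e - s >= min_len]
    if len(bursts) < n_reps:
        raise SegmentationError(
            f"detected {len(bursts)} movement bursts, expected {n_reps}"
        )
    if len(bursts) > n_reps:
        bursts = sorted(sorted(bursts, key=lambda b: b[0] - b[1])[:n_reps])
    guard = int(round(guard_s * angle.fs))
    bounds = []
    for k, (s, e) in enumerate(bursts):
        lo = max(0, s - guard)
        hi = min(theta.size, e + guard)
        if k > 0:
            lo = max(lo, (bursts[k - 1][1] + s) // 2)
        if k < len(bursts) - 1:
            hi = min(hi, (e + bursts[k + 1][0]) // 2)
        bounds.append((lo, hi))
    return bounds


def segment_epochs(
    angle: AngularSignal,
    n_reps: int,
    onset_frac: float = 0.1,
    guard_s: float = 0.5,
) -> list[Epoch]:
    """Split a multi-repetition trace into one epoch per movement burst."""
    return [
        Epoch(theta=angle.theta[lo:hi], fs=angle.fs, rep_index=k)
        for k, (lo, hi) in enumerate(segment_bounds(angle, n_reps, onset_frac, guard_s))
    ]


def preprocess_epoch(
    e: Epoch, arom_deg: float, rest_window_s: float = 0.25
) -> Epoch:
    """Baseline-remove and AROM-normalize one epoch.

    Subtracts the mean of the initial ``rest_window_s`` (the limb's resting
    position for this repetition) and divides by the subject's AROM, making
    epochs dimensionless and offset-invariant.
    """
    if arom_deg <= 0:
        raise InvalidParameterError("arom_deg must be positive")
    n_rest = max(1, int(round(rest_window_s * e.fs)))
    baseline = float(np.mean(e.theta[:n_rest]))
    return Epoch(theta=(e.theta - baseline) / arom_deg, fs=e.fs,
                 rep_index=e.rep_index)


def xcorr_normalized(th: Epoch, pt: Epoch) -> tuple[np.ndarray, np.ndarray]:
    """Normalized cross-correlation over all lags -(N-1)..(N-1).

    The shorter epoch is zero-padded to the common length first. Returns
    (lags in samples, sigma(m)); sigma(m) = sum_k th(k) pt(k+m) normalized
    by the geometric mean of the zero-lag autocorrelations.
    """
    if th.fs != pt.fs:
        raise InvalidParameterError("epochs must share a sampling rate")
    n = max(th.theta.size, pt.theta.size)
    a = np.pad(th.theta, (0, n - th.theta.size))
    b = np.pad(pt.theta, (0, n - pt.theta.size))
    denom = np.sqrt(np.dot(a, a) * np.dot(b, b))
    if denom == 0:
        raise UndefinedCorrelationError("zero-energy epoch")
    # np.correlate(b, a, 'full')[m + n - 1] = sum_k a(k) b(k + m)
    sigma = np.correlate(b, a, mode="full") / denom
    lags = np.arange(-(n - 1), n)
    return lags, sigma


def max_xcorr(th: Epoch, pt: Epoch) -> SimilarityResult:
    """Maximum over all lags of the normalized cross-correlation."""
    lags, sigma = xcorr_normalized(th, pt)
    k = int(np.argmax(sigma))
    return SimilarityResult(
        sigma=float(sigma[k]), lag_s=float(lags[k] / th.fs), rep_index=th.rep_index
    )


def session_similarity(
    th_angle: AngularSignal,
    pt_angle: AngularSignal,
    n_reps: int,
    profile: CalibrationProfile | None = None,
    th_arom_deg: float | None = None,
    pt_arom_deg: float | None = None,
    onset_frac: float = 0.1,
    guard_s: float = 0.5,
    rest_window_s: float = 0.25,
) -> tuple[list[SimilarityResult], dict]:
    """Segment, preprocess and correlate a full therapist/patient session.

    The repetition boundaries are detected on the therapist trace and the
    same sample windows are applied to the patient trace (both limbs move
    inside the same session timeline; the guard padding absorbs the
    stimulation lag). Each subject's epochs are normalized to that
    subject's own AROM. Returns the per-repetition results and a summary
    with the mean and standard deviation of sigma.
    """
    if th_angle.fs != pt_angle.fs:
        raise InvalidParameterError("traces must share a sampling rate")
    if th_angle.theta.size != pt_angle.theta.size:
        raise SegmentationError("therapist and patient traces cover different spans")
    if th_arom_deg is None:
        th_arom_deg = profile.arom_deg if profile and profile.arom_deg else None
    if th_arom_deg is None:
        th_arom_deg = float(th_angle.theta.max() - th_angle.theta.min())
    if pt_arom_deg is None:
        span = float(pt_angle.theta.max() - pt_angle.theta.min())
        pt_arom_deg = span if span > 0 else th_arom_deg

    bounds = segment_bounds(th_angle, n_reps, onset_frac, guard_s)
    results = []
    for k, (lo, hi) in enumerate(bounds):
        th_e = Epoch(theta=th_angle.theta[lo:hi], fs=th_angle.fs, rep_index=k)
        pt_e = Epoch(theta=pt_angle.theta[lo:hi], fs=pt_angle.fs, rep_index=k)
        th_p = preprocess_epoch(th_e, th_arom_deg, rest_window_s)
        pt_p = preprocess_epoch(pt_e, pt_arom_deg, rest_window_s)
        results.append(max_xcorr(th_p, pt_p))
    sigmas = np.array([r.sigma for r in results])
    summary = {
        "n_reps": len(results),
        "sigma_mean": float(sigmas.mean()),
        "sigma_sd": float(sigmas.std(ddof=1)) if len(results) > 1 else 0.0,
    }
    return results, summary


def write_similarity_report(
    path: str | Path, results: Sequence[SimilarityResult], summary: dict
) -> None:
    """Per-repetition CSV (`rep_index, sigma, lag_s`) + JSON summary sidecar."""
    import json

    path = Path(path)
    pd.DataFrame(
        {
            "rep_index": [r.rep_index for r in results],
            "sigma": [r.sigma for r in results],
            "lag_s": [r.lag_s for r in results],
        }
    ).to_csv(path, index=False)
    path.with_suffix(path.suffix + ".summary.json").write_text(
        json.dumps(summary, indent=2)
    )
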