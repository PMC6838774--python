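"""Filtering, magnitude computation, windowing and window gating.

Accelerometer streams are high-passed (2nd-order Butterworth, 0.25 Hz) to
remove the gravity component before movement features are computed; barometric
altitude is low-passed (2nd-order, 0.2 Hz) to suppress pressure noise.
Filtering is zero-phase (forward-backward) since the analysis is offline.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import signal as sps

from .constants import MIN_PER_DAY
from .data_model import ActivityWindow, DataError, SensorRecording

log = logging.getLogger(__name__)

ACCEL_HIGHPASS_HZ = 0.25
ALTITUDE_LOWPASS_HZ = 0.2

DROP_REASONS = ("missing_sensor", "missing_ee", "non_steady", "protocol_violation")


@dataclass(frozen=True)
class FilterSpec:
    kind: str  # "highpass" | "lowpass"
    order: int = 2
    cutoff: float = 0.25  # Hz
    zero_phase: bool = True

    def __post_init__(self) -> None:
        if self.kind not in ("highpass", "lowpass"):
            raise ValueError(f"unknown filter kind {self.kind!r}")
        if self.order < 1:
            raise ValueError("filter order must be >= 1")
        if self.cutoff <= 0:
            raise ValueError("cutoff must be positive")


ACCEL_FILTER = FilterSpec("highpass", 2, ACCEL_HIGHPASS_HZ)
ALTITUDE_FILTER = FilterSpec("lowpass", 2, ALTITUDE_LOWPASS_HZ)


def butterworth_filter(x: np.ndarray, fs: float, spec: FilterSpec) -> np.ndarray:
    """Apply a Butterworth filter of the given spec along axis 0."""
    x = np.asarray(x, dtype=float)
    if spec.cutoff >= fs / 2:
        raise ValueError(f"cutoff {spec.cutoff} Hz >= Nyquist ({fs / 2} Hz)")
    if x.shape[0] <= 3 * spec.order:
        raise ValueError("signal too short for the requested filter order")
    btype = "high" if spec.kind == "highpass" else "low"
    sos = sps.butter(spec.order, spec.cutoff, btype=btype, fs=fs, output="sos")
    if spec.zero_phase:
        return sps.sosfiltfilt(sos, x, axis=0)
    return sps.sosfilt(sos, x, axis=0)


def magnitude(xyz: np.ndarray) -> np.ndarray:
    """Per-sample Euclidean norm of a tri-axial (n, 3) signal."""
    xyz = np.asarray(xyz, dtype=float)
    if xyz.ndim != 2 or xyz.shape[1] != 3:
        raise ValueError("expected an (n, 3) tri-axial signal")
    return np.linalg.norm(xyz, axis=1)


def segment_activity(
    recordings: dict,
    activity_name: str,
    activity_class: str,
    subject_id: str,
    t_start: float,
    t_end: float,
    minute_range: tuple = (4, 8),
    window_seconds: float = 60.0,
) -> list:
    """Cut one activity bout into non-overlapping 60-s windows.

    Only minutes ``minute_range`` (half-open, relative to activity start) are
    used, so the metabolic steady state is established before any window
    begins. Activities shorter than the range yield fewer windows and a
    logged warning.
    """
    lo_min, hi_min = minute_range
    duration = t_end - t_start
    windows = []
    idx = 0
    for m in range(lo_min, hi_min):
        w0 = t_start + m * 60.0
        w1 = w0 + window_seconds
        if w1 > t_end + 1e-9:
            log.warning(
                "activity %s (%.1f min) shorter than minute range %s; produced %d windows",
                activity_name, duration / 60.0, minute_range, idx,
            )
            break
        signals = {site: rec.slice_time(w0, w1) for site, rec in recordings.items()}
        windows.append(ActivityWindow(
            subject_id=subject_id,
            activity_name=activity_name,
            activity_class=activity_class,
            window_index=idx,
            signals=signals,
            duration=window_seconds,
        ))
        idx += 1
    return windows


def measured_ree_from_series(
    ee_kcal_min: np.ndarray,
    t_minutes: np.ndarray,
    minute_range: tuple = (14, 18),
) -> float:
    """Resting EE as the mean of a per-minute EE series over ``minute_range``.

    Input is kcal/min sampled at times ``t_minutes`` (minutes from the start
    of the rest measurement); returns kcal/day.
    """
    ee = np.asarray(ee_kcal_min, dtype=float)
    t = np.asarray(t_minutes, dtype=float)
    lo, hi = minute_range
    if lo >= hi:
        raise DataError("empty minute range")
    mask = (t >= lo) & (t < hi)
    if not mask.any():
        raise DataError("EE series does not cover the REE minute range")
    return float(ee[mask].mean() * MIN_PER_DAY)


def steady_state_flag(
    ee_series: np.ndarray,
    next_window_mean: float | None = None,
    cv_threshold: float = 0.15,
    drift_threshold: float = 0.20,
) -> bool:
    """Reproducible stand-in for visual steady-state inspection.

    A window is steady when the coefficient of variation of its breath-level
    EE samples is below ``cv_threshold`` and, when the following window is
    available, its mean lies within ``drift_threshold`` of that window's mean.
    """
    ee = np.asarray(ee_series, dtype=float)
    m = ee.mean()
    if m <= 0:
        return False
    if ee.std(ddof=1) / m >= cv_threshold:
        return False
    if next_window_mean is not None and next_window_mean > 0:
        if abs(m - next_window_mean) / next_window_mean >= drift_threshold:
            return False
    return True


def gate_windows(windows: Sequence[ActivityWindow], expected_sites: Sequence[str] | None = None):
    """Split windows into (kept, dropped) with an enumerated reason per drop.

    Kept windows are complete, steady-state, and carry a measured EE; drop
    reasons are 'missing_sensor', 'missing_ee', 'non_steady', or
    'protocol_violation' (manual flag carried in ``ground_truth``).
    """
    kept, dropped = [], []
    for w in windows:
        if w.ground_truth.get("protocol_violation"):
            dropped.append((w, "protocol_violation"))
        elif expected_sites is not None and not set(expected_sites) <= set(w.signals.keys()):
            dropped.append((w, "missing_sensor"))
        elif not w.complete:
            dropped.append((w, "missing_sensor"))
        elif w.ee_meas is None:
            dropped.append((w, "missing_ee"))
        elif not w.steady_state:
            dropped.append((w, "non_steady"))
        else:
            kept.append(w)
    return kept, dropped
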