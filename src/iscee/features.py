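"""Per-window feature extraction: statistical features per sensor signal plus
high-level multi-sensor features (steps, distance, laterality, symmetry,
altitude change).

Feature naming convention
-------------------------
Statistical features are named ``STAT(signal_location)``, e.g.
``MEAN(a_M_DW)`` (mean acceleration magnitude, dominant wrist) or
``PERC_95(ω_Z_DA)`` (95th percentile of sagittal-plane angular velocity,
dominant ankle). Signals: ``a_M`` high-passed acceleration magnitude (g),
``ω_M`` angular-velocity magnitude (deg/s), ``ω_Z`` sagittal-plane angular
velocity (ankles only), ``H`` low-passed altitude (m). Locations are
dominance-relative (DW, NDW, DA, NDA, DF, NDF) or absolute (Ch chest,
Hi hip); dominance is resolved from the subject's handedness.
"""

from __future__ import annotations

import re
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import signal as sps

from .constants import STEP_LENGTH_FRACTION
from .data_model import ActivityWindow, DataError, SubjectProfile, resolve_site
from .preprocessing import (
    ACCEL_FILTER,
    ALTITUDE_FILTER,
    butterworth_filter,
    magnitude,
)

STATS = ("MEAN", "MEDIAN", "SD", "VAR", "RMS", "IQR",
         "PERC_1", "PERC_3", "PERC_5", "PERC_25", "PERC_75", "PERC_95", "PERC_99",
         "AC")
SIGNALS = ("a_M", "ω_M", "ω_Z", "H")
LOCATIONS = ("DW", "NDW", "DA", "NDA", "DF", "NDF", "Ch", "Hi")

HIGH_LEVEL_FEATURES = (
    "STEPS", "DIST", "STRIDE_VAR",
    "LAT_upper", "LAT_lower_ankle", "LAT_feet", "LAT_upper_vs_lower",
    "CORR_wrists", "CORR_ankles", "CORR_feet",
    "ALT_CHANGE", "AC_total",
)

DEMOGRAPHIC_FEATURES = ("age", "weight", "height", "sex_male", "sport_hours_per_week")

_NAME_RE = re.compile(
    r"^(?P<stat>MEAN|MEDIAN|SD|VAR|RMS|IQR|PERC_(?:1|3|5|25|75|95|99)|AC)"
    r"\((?P<signal>a_M|ω_M|ω_Z|H)_(?P<loc>DW|NDW|DA|NDA|DF|NDF|Ch|Hi)\)$"
)

# Step detection parameters (peak detection on ankle sagittal gyro).
STEP_LOWPASS_HZ = 5.0
STEP_MIN_HEIGHT = 20.0       # deg/s absolute floor
STEP_REL_HEIGHT = 0.3        # fraction of the window's 95th percentile
STEP_REFRACTORY_S = 0.3      # minimum inter-peak gap


def parse_feature_name(name: str) -> tuple:
    """Parse ``STAT(signal_location)`` into (stat, signal, location).

    Raises DataError for names outside the grammar.
    """
    m = _NAME_RE.match(name)
    if m is None:
        raise DataError(f"feature name {name!r} does not match STAT(signal_location)")
    sig, loc = m["signal"], m["loc"]
    if sig == "ω_Z" and loc not in ("DA", "NDA"):
        raise DataError(f"{name!r}: sagittal angular velocity is defined for ankles only")
    return m["stat"], sig, loc


def feature_name(stat: str, signal: str, location: str) -> str:
    return f"{stat}({signal}_{location})"


def statistical_features(x: np.ndarray, fs: float | None = None,
                         stats: Iterable[str] = STATS) -> dict:
    """Compute the named summary statistics of a scalar series.

    SD/VAR use the n-1 denominator; percentiles use linear interpolation
    between order statistics. ``AC`` (activity counts, see
    :func:`activity_counts`) needs ``fs`` and is skipped when fs is None.
    """
    x = np.asarray(x, dtype=float)
    if x.size < 2:
        raise ValueError("series must have at least 2 samples")
    out = {}
    pcts = sorted({int(s.split("_")[1]) for s in stats if s.startswith("PERC_")})
    pct_vals = dict(zip(pcts, np.percentile(x, pcts))) if pcts else {}
    for s in stats:
        if s == "MEAN":
            out[s] = float(x.mean())
        elif s == "MEDIAN":
            out[s] = float(np.median(x))
        elif s == "SD":
            out[s] = float(x.std(ddof=1))
        elif s == "VAR":
            out[s] = float(x.var(ddof=1))
        elif s == "RMS":
            out[s] = float(np.sqrt(np.mean(x**2)))
        elif s == "IQR":
            q75, q25 = np.percentile(x, [75, 25])
            out[s] = float(q75 - q25)
        elif s.startswith("PERC_"):
            out[s] = float(pct_vals[int(s.split("_")[1])])
        elif s == "AC":
            if fs is not None:
                out[s] = activity_counts(x, fs)
        else:
            raise ValueError(f"unknown statistic {s!r}")
    return out


def activity_counts(x: np.ndarray, fs: float) -> float:
    """Activity counts: time-integral of the rectified signal, in signal·s.

    For high-pass-filtered acceleration magnitude this is a device-independent
    movement-intensity summary that is linear in amplitude.
    """
    x = np.asarray(x, dtype=float)
    return float(np.sum(np.abs(x)) / fs)


def detect_steps(gyro_z: np.ndarray, fs: float) -> np.ndarray:
    """Detect step events (one per ipsilateral step) from ankle sagittal gyro.

    The signal is low-passed at 5 Hz; local maxima count as steps when they
    exceed max(20 deg/s, 0.3 x the window's 95th percentile) and are at least
    0.3 s apart. Returns event times in seconds relative to the window start.
    """
    x = np.asarray(gyro_z, dtype=float)
    if x.size < 10:
        return np.empty(0)
    if STEP_LOWPASS_HZ < fs / 2:
        sos = sps.butter(2, STEP_LOWPASS_HZ, btype="low", fs=fs, output="sos")
        x = sps.sosfiltfilt(sos, x)
    height = max(STEP_MIN_HEIGHT, STEP_REL_HEIGHT * float(np.percentile(x, 95)))
    peaks, _ = sps.find_peaks(x, height=height, distance=max(1, int(round(STEP_REFRACTORY_S * fs))))
    return peaks / fs


def step_length(subject: SubjectProfile) -> float:
    """Static-method step length estimate: a sex-specific fraction of height."""
    if subject.height is None or subject.height <= 0:
        raise DataError("subject height required for step length")
    return STEP_LENGTH_FRACTION[subject.sex] * subject.height


def distance(n_steps: int, step_length_m: float) -> float:
    """Distance walked (m) = step count x step length."""
    return n_steps * step_length_m


def stride_time_variance(events_per_leg: Sequence[np.ndarray]) -> float:
    """Sample variance (s^2) of same-leg inter-step intervals, pooled over legs.

    Legs with fewer than 3 events contribute nothing; returns NaN when fewer
    than 2 intervals are available in total.
    """
    intervals = []
    for ev in events_per_leg:
        ev = np.asarray(ev, dtype=float)
        if ev.size >= 3:
            intervals.append(np.diff(ev))
    if not intervals:
        return float("nan")
    pooled = np.concatenate(intervals)
    if pooled.size < 2:
        return float("nan")
    return float(pooled.var(ddof=1))


def laterality_index(ac_dominant: float, ac_nondominant: float) -> float:
    """Symmetric limb-use laterality in [-1, 1].

    (AC_dom - AC_nondom) / (AC_dom + AC_nondom); 0 when both sides are zero.
    Positive values indicate dominant-side preference.
    """
    if ac_dominant < 0 or ac_nondominant < 0:
        raise ValueError("activity counts must be non-negative")
    total = ac_dominant + ac_nondominant
    if total == 0:
        return 0.0
    return (ac_dominant - ac_nondominant) / total


def cross_correlation_feature(left: np.ndarray, right: np.ndarray, fs: float,
                              max_lag_s: float = 1.0) -> float:
    """Maximum normalized cross-correlation of two limb signals within ±1 s.

    Both signals are mean-removed; normalization is by the product of their
    standard deviations, so identical signals give 1 at lag 0. Zero-variance
    input returns 0 by convention.
    """
    x = np.asarray(left, dtype=float)
    y = np.asarray(right, dtype=float)
    if x.shape != y.shape:
        raise ValueError("signals must have equal length")
    x = x - x.mean()
    y = y - y.mean()
    nx, ny = np.linalg.norm(x), np.linalg.norm(y)
    if nx == 0 or ny == 0:
        return 0.0
    max_lag = int(round(max_lag_s * fs))
    full = sps.correlate(x, y, mode="full")
    mid = len(x) - 1
    lo, hi = mid - max_lag, mid + max_lag + 1
    return float(np.max(full[lo:hi]) / (nx * ny))


def altitude_change(filtered_alt: np.ndarray) -> float:
    """Net signed altitude change over the window (last minus first sample)."""
    alt = np.asarray(filtered_alt, dtype=float)
    if alt.size == 0:
        return 0.0
    return float(alt[-1] - alt[0])


# ---------------------------------------------------------------------------
# Feature-table assembly
# ---------------------------------------------------------------------------

def _derived_series(window: ActivityWindow) -> dict:
    """Compute per-site derived base series for one window.

    Returns {(signal, site): array}. Acceleration is high-pass filtered
    (gravity removal), altitude low-pass filtered; the gyroscope is used raw.
    """
    out = {}
    for site, rec in window.signals.items():
        acc_f = butterworth_filter(rec.acc, rec.fs, ACCEL_FILTER)
        out[("a_M", site)] = magnitude(acc_f)
        out[("ω_M", site)] = magnitude(rec.gyro)
        out[("H", site)] = butterworth_filter(rec.alt, rec.fs, ALTITUDE_FILTER)
        if site.startswith("ankle"):
            out[("ω_Z", site)] = rec.gyro[:, 2]
    return out


def default_feature_bank(score_names: Sequence[str] = (), include_ree: bool = True) -> list:
    """The full default feature bank (statistical + high-level + demographics)."""
    names = []
    for loc in LOCATIONS:
        sigs = ["a_M", "ω_M", "H"] + (["ω_Z"] if loc in ("DA", "NDA") else [])
        for sig in sigs:
            for stat in STATS:
                names.append(feature_name(stat, sig, loc))
    names.extend(HIGH_LEVEL_FEATURES)
    names.extend(DEMOGRAPHIC_FEATURES)
    names.extend(score_names)
    if include_ree:
        names.append("REE")
    return names


def window_features(window: ActivityWindow, subject: SubjectProfile,
                    names: Sequence[str]) -> dict:
    """Compute the requested features for one window. Missing -> NaN."""
    fs = next(iter(window.signals.values())).fs if window.signals else None
    series = _derived_series(window)
    hand = subject.handedness

    def get_series(signal: str, loc: str):
        site = resolve_site(loc, hand)
        return series.get((signal, site))

    # step events are shared by several high-level features
    needs_steps = any(n in ("STEPS", "DIST", "STRIDE_VAR") for n in names)
    step_events = None
    if needs_steps:
        step_events = []
        for site in ("ankle_L", "ankle_R"):
            key = ("ω_Z", site)
            step_events.append(detect_steps(series[key], fs) if key in series else np.empty(0))

    def ac_for(site: str) -> float:
        key = ("a_M", site)
        return activity_counts(series[key], fs) if key in series else float("nan")

    dom = subject.dominant_side()
    non = "L" if dom == "R" else "R"

    out = {}
    for name in names:
        if _NAME_RE.match(name):
            stat, sig, loc = parse_feature_name(name)
            x = get_series(sig, loc)
            if x is None:
                out[name] = float("nan")
            elif stat == "AC":
                out[name] = activity_counts(x, fs)
            else:
                out[name] = statistical_features(x, stats=[stat])[stat]
        elif name == "STEPS":
            out[name] = float(sum(len(ev) for ev in step_events))
        elif name == "DIST":
            n_steps = int(sum(len(ev) for ev in step_events))
            out[name] = distance(n_steps, step_length(subject))
        elif name == "STRIDE_VAR":
            out[name] = stride_time_variance(step_events)
        elif name == "LAT_upper":
            out[name] = laterality_index(ac_for(f"wrist_{dom}"), ac_for(f"wrist_{non}"))
        elif name == "LAT_lower_ankle":
            out[name] = laterality_index(ac_for(f"ankle_{dom}"), ac_for(f"ankle_{non}"))
        elif name == "LAT_feet":
            out[name] = laterality_index(ac_for(f"foot_{dom}"), ac_for(f"foot_{non}"))
        elif name == "LAT_upper_vs_lower":
            upper = ac_for("wrist_L") + ac_for("wrist_R")
            lower = ac_for("ankle_L") + ac_for("ankle_R")
            out[name] = laterality_index(upper, lower)
        elif name in ("CORR_wrists", "CORR_ankles", "CORR_feet"):
            base = {"CORR_wrists": "wrist", "CORR_ankles": "ankle", "CORR_feet": "foot"}[name]
            xl = series.get(("a_M", f"{base}_L"))
            xr = series.get(("a_M", f"{base}_R"))
            out[name] = (cross_correlation_feature(xl, xr, fs)
                         if xl is not None and xr is not None else float("nan"))
        elif name == "ALT_CHANGE":
            alt = series.get(("H", "chest"))
            if alt is None and series:
                alt = next((v for (s, _), v in series.items() if s == "H"), None)
            out[name] = altitude_change(alt) if alt is not None else float("nan")
        elif name == "AC_total":
            out[name] = float(np.nansum([ac_for(s) for s in window.signals.keys()]))
        elif name == "age":
            out[name] = float(subject.age)
        elif name == "weight":
            out[name] = float(subject.weight)
        elif name == "height":
            out[name] = float(subject.height)
        elif name == "sex_male":
            out[name] = 1.0 if subject.sex == "male" else 0.0
        elif name == "sport_hours_per_week":
            out[name] = float(subject.sport_hours_per_week)
        elif name == "REE":
            out[name] = float(subject.ree_est) if subject.ree_est is not None else float("nan")
        elif name in subject.scores:
            out[name] = float(subject.scores[name])
        else:
            raise DataError(f"unknown feature {name!r} requested")
    return out


def assemble_feature_table(windows: Sequence[ActivityWindow],
                           subjects: Sequence[SubjectProfile],
                           features: Sequence[str] | None = None,
                           include_ree: bool = True) -> pd.DataFrame:
    """One row per window with the requested (or full default) feature bank.

    The returned frame also carries ``subject_id``, ``activity_name``,
    ``activity_class`` and ``ee_meas`` index columns for downstream model
    fitting and evaluation.
    """
    by_id = {s.id: s for s in subjects}
    if features is None:
        score_names = sorted({k for s in subjects for k in s.scores})
        features = default_feature_bank(score_names, include_ree=include_ree)
    rows = []
    for w in windows:
        subj = by_id[w.subject_id]
        row = window_features(w, subj, features)
        row["subject_id"] = w.subject_id
        row["activity_name"] = w.activity_name
        row["activity_class"] = w.activity_class
        row["ee_meas"] = w.ee_meas if w.ee_meas is not None else float("nan")
        rows.append(row)
    meta = ["subject_id", "activity_name", "activity_class", "ee_meas"]
    return pd.DataFrame(rows, columns=meta + list(features))
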