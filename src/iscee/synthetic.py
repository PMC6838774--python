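"""Seeded virtual cohorts: subjects, 8-site IMU signals per activity window,
ground-truth step events and calorimetry-style EE labels.

The generator emulates the statistical structure the estimation pipeline
assumes — demographics matching the study cohort, four activity classes with
class-specific movement signatures, a speed-cadence mapping for walking, and
MET-calibrated EE anchored to each subject's resting EE — without attempting
biomechanical realism. Movement amplitude scales with the drawn MET, so
sensor features are genuinely informative about EE within each class.

Signal morphology is deliberately simple: sums of windowed sinusoids,
gaussian swing bursts, impacts and white noise on top of gravity.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .constants import CADENCE_BY_SPEED, met_to_ee
from .data_model import (
    ActivityWindow,
    SENSOR_SITES,
    SensorRecording,
    SessionDataset,
    SubjectProfile,
)
from .features import assemble_feature_table
from .preprocessing import gate_windows
from .ree import estimate_ree

#: activity -> (class, MET mean, MET sd); walking entries carry speed in km/h.
DEFAULT_ACTIVITIES: Mapping[str, tuple] = {
    "rest": ("sedentary", 0.9, 0.2),
    "watching_tv": ("sedentary", 1.3, 0.2),
    "computer_work": ("sedentary", 1.2, 0.2),
    "riding_elevator": ("low_intensity", 1.5, 0.3),
    "washing_dishes": ("low_intensity", 2.4, 0.6),
    "vacuum_cleaning": ("low_intensity", 3.2, 0.6),
    "weight_lifting": ("high_intensity", 2.0, 0.6),
    "table_tennis": ("high_intensity", 4.5, 1.2),
    "badminton": ("high_intensity", 6.0, 1.8),
    "walking_1kmh": ("walking", 2.5, 0.5),
    "walking_4kmh": ("walking", 4.0, 0.9),
    "climbing_stairs": ("walking", 7.1, 1.7),
}

WALKING_SPEEDS = {"walking_1kmh": 1, "walking_4kmh": 4}
STAIR_CLIMB_RATE_M_PER_MIN = 3.0
STAIR_CADENCE = 90.0


@dataclass
class SimConfig:
    n_subjects: int = 30
    seed: int = 0
    fs: float = 50.0
    window_seconds: float = 60.0
    windows_per_activity: int = 4
    activities: Mapping[str, tuple] = field(default_factory=lambda: dict(DEFAULT_ACTIVITIES))
    cadence_table: Mapping[int, float] = field(default_factory=lambda: dict(CADENCE_BY_SPEED))
    ee_rel_sd: float = 0.05          # per-window relative noise on measured EE
    ree_rel_sd: float = 0.10         # relative error of measured vs equation REE
    gait_jitter_sd: float = 0.02     # s, SD of step-time jitter
    acc_noise_g: float = 0.02
    gyro_noise_dps: float = 1.5
    alt_noise_m: float = 0.2
    dropout_rate: float = 140.0 / 1440.0   # expected fraction of windows removed

    def __post_init__(self) -> None:
        for v in (self.ee_rel_sd, self.ree_rel_sd, self.gait_jitter_sd,
                  self.acc_noise_g, self.gyro_noise_dps, self.alt_noise_m):
            if v < 0:
                raise ValueError("noise levels must be non-negative")
        for name, (cls, mean, sd) in self.activities.items():
            if mean <= 0.5:
                raise ValueError(f"MET mean for {name} must exceed 0.5")


def _truncated_normal(rng, mean, sd, lo, hi):
    for _ in range(1000):
        x = rng.normal(mean, sd)
        if lo <= x <= hi:
            return float(x)
    return float(np.clip(mean, lo, hi))


def simulate_subject(config: SimConfig, index: int,
                     rng: np.random.Generator) -> SubjectProfile:
    """Draw one subject: demographics from truncated normals matching the
    study cohort, sex 2:1 male, measured REE = equation x (1 + noise)."""
    sex = "male" if rng.random() < 2.0 / 3.0 else "female"
    subj = SubjectProfile(
        id=f"S{index:02d}",
        age=_truncated_normal(rng, 54.1, 11.9, 27, 72),
        sex=sex,
        weight=_truncated_normal(rng, 75.5, 16.2, 44, 106),
        height=_truncated_normal(rng, 1.71, 0.09, 1.48, 1.91),
        handedness="right" if rng.random() < 0.9 else "left",
        sport_hours_per_week=_truncated_normal(rng, 3.9, 3.6, 0, 14),
        scores={
            "scim3_mobility": _truncated_normal(rng, 28.1, 3.9, 15, 30),
            "six_mwt_m": _truncated_normal(rng, 486, 158, 137, 744),
            "tetraparetic": float(rng.random() < 1.0 / 3.0),
        },
    )
    ree_eq = estimate_ree(subj, "updated_harris_benedict")
    subj.ree_meas = ree_eq * (1.0 + config.ree_rel_sd * rng.standard_normal())
    if subj.ree_meas <= 0:
        subj.ree_meas = ree_eq
    return subj


# ---------------------------------------------------------------------------
# signal synthesis helpers
# ---------------------------------------------------------------------------

def _gait_events(rng, duration, per_leg_interval, jitter_sd, phase_offset):
    """Jittered per-leg step event times over [0, duration)."""
    times = []
    t = phase_offset + abs(rng.normal(0, jitter_sd))
    while t < duration:
        times.append(t)
        t += per_leg_interval + rng.normal(0, jitter_sd)
    return np.array(times)


def _burst_train(t, events, amplitude, width):
    """Sum of gaussian bursts centered at the event times."""
    x = np.zeros_like(t)
    if len(events) == 0:
        return x
    fs = 1.0 / (t[1] - t[0])
    half = int(np.ceil(4 * width * fs))
    for ev in events:
        c = int(round(ev * fs))
        lo, hi = max(0, c - half), min(len(t), c + half + 1)
        x[lo:hi] += amplitude * np.exp(-0.5 * ((t[lo:hi] - ev) / width) ** 2)
    return x


def _intermittent_mask(rng, t, duty=0.4, segment_s=4.0):
    """0/1 activity envelope with ~``duty`` on-fraction in multi-second bouts."""
    n_seg = int(np.ceil(t[-1] / segment_s)) + 1
    on = (rng.random(n_seg) < duty).astype(float)
    idx = np.minimum((t / segment_s).astype(int), n_seg - 1)
    return on[idx]


def _empty_site(site, t, fs, rng, cfg, alt_base):
    n = len(t)
    acc = rng.normal(0, cfg.acc_noise_g, size=(n, 3))
    acc[:, 2] += 1.0  # gravity
    gyro = rng.normal(0, cfg.gyro_noise_dps, size=(n, 3))
    alt = alt_base + rng.normal(0, cfg.alt_noise_m, size=n)
    return SensorRecording(site=site, t=t.copy(), acc=acc, gyro=gyro, alt=alt, fs=fs)


def simulate_activity_window(subject: SubjectProfile, activity: str,
                             config: SimConfig, rng: np.random.Generator,
                             window_index: int = 0) -> ActivityWindow:
    """Generate one 60-s labeled window with ground-truth sidecar.

    The drawn MET sets both the EE label (via the shared MET-EE conversion)
    and the movement amplitude scale, so windows that cost more energy also
    move more.
    """
    if activity not in config.activities:
        raise KeyError(f"unknown activity {activity!r}")
    cls, met_mean, met_sd = config.activities[activity]
    fs = config.fs
    dur = config.window_seconds
    n = int(round(dur * fs))
    t = np.arange(n) / fs

    met = max(0.5, rng.normal(met_mean, met_sd))
    # Movement amplitude scales with absolute intensity relative to a per-class
    # reference (the class's mean MET over its activities), so windows that
    # cost more energy also move more — across activities, not just within one.
    class_mets = [m for (c, m, _) in config.activities.values() if c == cls]
    f = met / float(np.mean(class_mets))
    subj_amp = np.exp(rng.normal(0, 0.15))  # subject/session-level variability
    f *= subj_amp

    alt_base = 400.0 + 10.0 * rng.standard_normal()
    recs = {site: _empty_site(site, t, fs, rng, config, alt_base)
            for site in SENSOR_SITES}
    step_events = {"ankle_L": np.empty(0), "ankle_R": np.empty(0)}

    if cls == "walking":
        if activity == "climbing_stairs":
            cadence = STAIR_CADENCE
            climb = STAIR_CLIMB_RATE_M_PER_MIN
        else:
            cadence = float(config.cadence_table[WALKING_SPEEDS[activity]])
            climb = 0.0
        per_leg = 2 * 60.0 / cadence
        ev_l = _gait_events(rng, dur, per_leg, config.gait_jitter_sd, 0.05)
        ev_r = _gait_events(rng, dur, per_leg, config.gait_jitter_sd, 0.05 + per_leg / 2)
        step_events = {"ankle_L": ev_l, "ankle_R": ev_r}
        stride_hz = cadence / 120.0
        step_hz = cadence / 60.0
        for side, ev in (("L", ev_l), ("R", ev_r)):
            swing = _burst_train(t, ev, 200.0 * f, 0.10)
            recs[f"ankle_{side}"].gyro[:, 2] += swing
            recs[f"ankle_{side}"].gyro[:, 0] += 0.2 * swing
            recs[f"ankle_{side}"].acc[:, 0] += _burst_train(t, ev, 0.5 * f, 0.05)
            recs[f"foot_{side}"].acc[:, 2] += _burst_train(t, ev, 0.8 * f, 0.04)
            recs[f"foot_{side}"].gyro[:, 1] += _burst_train(t, ev, 150.0 * f, 0.08)
            # arm swing, contralateral phase; swing amplitude is mostly a
            # personal gait trait and barely tracks walking intensity
            arm = 35.0 * subj_amp * (0.8 + 0.2 * f)
            ph = 0.0 if side == "L" else np.pi
            recs[f"wrist_{side}"].gyro[:, 1] += arm * np.sin(2 * np.pi * stride_hz * t + ph)
            recs[f"wrist_{side}"].acc[:, 0] += arm / 580.0 * np.sin(2 * np.pi * stride_hz * t + ph)
        for site in ("chest", "hip"):
            recs[site].acc[:, 2] += 0.12 * f * np.sin(2 * np.pi * step_hz * t)
            recs[site].gyro[:, 0] += 12.0 * f * np.sin(2 * np.pi * stride_hz * t)
        if climb > 0:
            ramp = climb / 60.0 * t
            for site in SENSOR_SITES:
                recs[site].alt += ramp
    elif cls == "high_intensity":
        # near-sustained multi-site movement; intermittent pauses (rallies,
        # rest between sets) and amplitude tied to intensity mean that light
        # high-intensity activities (weight lifting) overlap with the
        # low-intensity class, as they do in real recordings
        env = _intermittent_mask(rng, t, duty=0.85, segment_s=5.0)
        for side in ("L", "R"):
            ph = rng.uniform(0, 2 * np.pi)
            recs[f"wrist_{side}"].gyro[:, 0] += 62.0 * f * env * np.abs(
                np.sin(2 * np.pi * 1.2 * t + ph))
            recs[f"wrist_{side}"].acc[:, 0] += 0.3 * f * env * np.sin(2 * np.pi * 1.2 * t + ph)
            recs[f"ankle_{side}"].gyro[:, 2] += 12.0 * f * env * np.sin(2 * np.pi * 0.8 * t + ph)
            recs[f"ankle_{side}"].acc[:, 1] += 0.15 * f * env * np.sin(2 * np.pi * 0.8 * t + ph)
            recs[f"foot_{side}"].acc[:, 2] += 0.12 * f * env * np.sin(2 * np.pi * 0.8 * t + ph)
        recs["chest"].gyro[:, 1] += 30.0 * f * env * np.abs(np.sin(2 * np.pi * 0.9 * t))
        recs["chest"].acc[:, 2] += 0.20 * f * env * np.sin(2 * np.pi * 1.8 * t)
        recs["hip"].acc[:, 2] += 0.16 * f * env * np.sin(2 * np.pi * 1.8 * t)
        recs["hip"].gyro[:, 1] += 18.0 * f * env * np.abs(np.sin(2 * np.pi * 0.9 * t))
    elif cls == "low_intensity":
        # intermittent, mostly upper-limb movement
        env = _intermittent_mask(rng, t, duty=0.4)
        dom = subject.dominant_side()
        for side in ("L", "R"):
            amp = 1.0 if side == dom else 0.6
            ph = rng.uniform(0, 2 * np.pi)
            recs[f"wrist_{side}"].gyro[:, 0] += 40.0 * f * amp * env * np.abs(
                np.sin(2 * np.pi * 1.0 * t + ph))
            recs[f"wrist_{side}"].acc[:, 0] += 0.12 * f * amp * env * np.sin(
                2 * np.pi * 1.0 * t + ph)
        recs["chest"].gyro[:, 1] += 8.0 * f * env * np.abs(np.sin(2 * np.pi * 0.6 * t))
        recs["chest"].acc[:, 2] += 0.06 * f * env * np.sin(2 * np.pi * 1.0 * t)
        recs["hip"].acc[:, 2] += 0.05 * f * env * np.sin(2 * np.pi * 1.0 * t)
    else:  # sedentary: occasional tiny fidgets
        env = _intermittent_mask(rng, t, duty=0.1, segment_s=6.0)
        for side in ("L", "R"):
            recs[f"wrist_{side}"].gyro[:, 0] += 6.0 * f * env * np.abs(
                np.sin(2 * np.pi * 0.8 * t))
            recs[f"wrist_{side}"].acc[:, 0] += 0.02 * f * env * np.sin(2 * np.pi * 0.8 * t)

    ee = met_to_ee(met, subject.weight)
    ee_meas = ee * (1.0 + config.ee_rel_sd * rng.standard_normal())
    if ee_meas <= 0:
        ee_meas = ee
    return ActivityWindow(
        subject_id=subject.id,
        activity_name=activity,
        activity_class=cls,
        window_index=window_index,
        signals=recs,
        ee_meas=float(ee_meas),
        ground_truth={
            "met": float(met),
            "true_ee": float(ee),
            "step_events_L": step_events["ankle_L"].tolist(),
            "step_events_R": step_events["ankle_R"].tolist(),
            "n_steps": int(len(step_events["ankle_L"]) + len(step_events["ankle_R"])),
        },
    )


def _inject_dropout(window: ActivityWindow, rng: np.random.Generator) -> ActivityWindow:
    """Randomly damage a window: lose a sensor, the EE label, or steadiness."""
    kind = rng.choice(["missing_sensor", "missing_ee", "non_steady"])
    window.ground_truth["injected_dropout"] = str(kind)
    if kind == "missing_sensor":
        site = rng.choice(list(window.signals.keys()))
        signals = dict(window.signals)
        del signals[site]
        window.signals = signals
        window.complete = False
    elif kind == "missing_ee":
        window.ee_meas = None
    else:
        window.steady_state = False
    return window


def simulate_cohort(config: SimConfig | None = None) -> SessionDataset:
    """Simulate the full cohort: subjects x activities x windows, with
    dropout injection at the configured rate. Deterministic per seed."""
    config = config or SimConfig()
    ss = np.random.SeedSequence(config.seed)
    subj_ss, win_ss = ss.spawn(2)
    subj_rngs = subj_ss.spawn(config.n_subjects)
    subjects = [simulate_subject(config, i, np.random.default_rng(r))
                for i, r in enumerate(subj_rngs)]
    windows = []
    win_children = win_ss.spawn(config.n_subjects)
    for subj, child in zip(subjects, win_children):
        rng = np.random.default_rng(child)
        for activity in config.activities:
            for widx in range(config.windows_per_activity):
                w = simulate_activity_window(subj, activity, config, rng, widx)
                if rng.random() < config.dropout_rate:
                    w = _inject_dropout(w, rng)
                windows.append(w)
    return SessionDataset(subjects=subjects, windows=windows)


def simulate_feature_table(config: SimConfig | None = None,
                           features: Sequence[str] | None = None,
                           ree_model: str = "updated_harris_benedict"):
    """Streaming simulate -> gate -> featurize, discarding raw signals.

    Memory-friendly path for cohort-scale runs: windows are generated one at
    a time and only their feature rows are kept. Returns
    (feature table of kept windows, gating info dict).
    """
    config = config or SimConfig()
    ss = np.random.SeedSequence(config.seed)
    subj_ss, win_ss = ss.spawn(2)
    subjects = [simulate_subject(config, i, np.random.default_rng(r))
                for i, r in enumerate(subj_ss.spawn(config.n_subjects))]
    for s in subjects:
        s.ree_est = estimate_ree(s, ree_model)
    frames = []
    n_candidates = 0
    drop_reasons: dict = {}
    for subj, child in zip(subjects, win_ss.spawn(config.n_subjects)):
        rng = np.random.default_rng(child)
        for activity in config.activities:
            for widx in range(config.windows_per_activity):
                w = simulate_activity_window(subj, activity, config, rng, widx)
                if rng.random() < config.dropout_rate:
                    w = _inject_dropout(w, rng)
                n_candidates += 1
                kept, dropped = gate_windows([w], expected_sites=SENSOR_SITES)
                if dropped:
                    reason = dropped[0][1]
                    drop_reasons[reason] = drop_reasons.get(reason, 0) + 1
                    continue
                frames.append(assemble_feature_table(kept, [subj], features=features))
    table = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame()
    info = {
        "n_candidates": n_candidates,
        "n_kept": len(table),
        "retention": len(table) / n_candidates if n_candidates else float("nan"),
        "drop_reasons": drop_reasons,
        "subjects": subjects,
    }
    return table, info
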