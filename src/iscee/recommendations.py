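"""Translation of institutional physical-activity guidelines into daily step
and time goals for ambulatory individuals with an incomplete spinal cord
injury.

A :class:`SpeedProfile` carries the measured per-speed quantities (energy
cost of 30 min of walking, cadence, resting and measured daily EE). Guideline
presets are expressed either in minutes of moderate activity or in kcal of
additional EE; the translation is simple proportional arithmetic, rounded
half-away-from-zero to integer minutes/steps exactly once at output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

from .data_model import DataError


def _round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


@dataclass(frozen=True)
class SpeedProfile:
    """Measured walking economy at one speed (or a cohort average)."""

    speed: float | str            # km/h, or "average ..." label
    cadence: float                # steps/min
    ree: float                    # kcal/day
    measured_ee: float            # kcal/day during walking at this speed
    ee_per_30min: float | None = None  # kcal of additional EE per 30 min

    def __post_init__(self) -> None:
        if self.cadence <= 0 or self.ree <= 0 or self.measured_ee <= 0:
            raise DataError("profile quantities must be positive")
        if self.ee_per_30min is not None and self.ee_per_30min <= 0:
            raise DataError("ee_per_30min must be positive when present")


#: Measured speed profiles (speeds in km/h). ``ee_per_30min`` is the energy
#: spent in 30 min of walking above rest; for 1-2 km/h only the slower-paced
#: goal rows were measured, so no 30-min energy cost is attached.
STUDY_SPEED_PROFILES: Mapping[float | str, SpeedProfile] = {
    1: SpeedProfile(1, cadence=56, ree=1477, measured_ee=3971),
    2: SpeedProfile(2, cadence=76, ree=1661, measured_ee=4894),
    3: SpeedProfile(3, cadence=88, ree=1557, measured_ee=5579, ee_per_30min=84),
    4: SpeedProfile(4, cadence=105, ree=1814, measured_ee=8566, ee_per_30min=141),
    5: SpeedProfile(5, cadence=113, ree=1653, measured_ee=7737, ee_per_30min=127),
    6: SpeedProfile(6, cadence=124, ree=1895, measured_ee=9859, ee_per_30min=160),
    "average_moderate": SpeedProfile("average 4.3", cadence=104, ree=1685,
                                     measured_ee=7422, ee_per_30min=120),
    "average_all": SpeedProfile("average 3.3", cadence=91, ree=1641,
                                measured_ee=6359),
}

#: Guideline presets: label -> (basis kind, basis value, speeds to evaluate).
GUIDELINE_PRESETS = {
    "30min": ("minutes", 30, (3, 4, 5, 6, "average_moderate")),
    "75kcal": ("kcal", 75, (3, 4, 5, 6, "average_moderate")),
    "60min": ("minutes", 60, ("average_moderate",)),
    "150kcal": ("kcal", 150, ("average_moderate",)),
    "300kcal": ("kcal", 300, (1, 2, 3, 4, 5, 6, "average_all")),
    "569kcal": ("kcal", 569, ("average_moderate",)),
}


def additional_daily_ee(profile: SpeedProfile) -> float:
    """Activity-attributable EE: measured daily EE minus resting EE (kcal/day)."""
    diff = profile.measured_ee - profile.ree
    if diff < 0:
        raise DataError("measured EE below resting EE")
    return diff


def effective_ee_per_30min(profile: SpeedProfile) -> float:
    """Energy cost of 30 min of walking at this speed, above rest.

    Uses the measured per-30-min value when available; otherwise derives it
    from the additional daily EE (48 half-hours per day), which is how the
    two quantities relate for steady walking.
    """
    if profile.ee_per_30min is not None:
        return profile.ee_per_30min
    return additional_daily_ee(profile) / 48.0


def minutes_for_energy(target_kcal: float, profile: SpeedProfile) -> int:
    """Walking minutes needed to spend ``target_kcal`` at this speed."""
    if target_kcal <= 0:
        raise ValueError("target energy must be positive")
    return _round_half_away(minutes_for_energy_unrounded(target_kcal, profile))


def minutes_for_energy_unrounded(target_kcal: float, profile: SpeedProfile) -> float:
    return target_kcal / effective_ee_per_30min(profile) * 30.0


def steps_for_minutes(minutes: float, cadence: float) -> int:
    """Step goal for a walking duration at a given cadence."""
    if minutes < 0 or cadence < 0:
        raise ValueError("minutes and cadence must be non-negative")
    return _round_half_away(minutes * cadence)


@dataclass(frozen=True)
class RecommendationRow:
    recommendation: str
    basis: str                    # "minutes" | "kcal"
    basis_value: float
    speed: float | str
    goal_minutes: float
    goal_steps: int
    energy_kcal: float | None     # kcal spent in goal_minutes (when derivable)
    cadence: float
    ree: float
    measured_ee: float
    additional_ee: float


def build_translation_table(
    presets: Sequence[str] | None = None,
    profiles: Mapping | None = None,
) -> list:
    """One row per (guideline preset, speed), mirroring the study's table.

    Minute-based presets report the energy spent in that time; kcal-based
    presets report the minutes (and steps) needed to spend that energy.
    """
    profiles = profiles if profiles is not None else STUDY_SPEED_PROFILES
    presets = list(presets) if presets is not None else list(GUIDELINE_PRESETS)
    rows = []
    for label in presets:
        if label not in GUIDELINE_PRESETS:
            raise DataError(f"unknown guideline preset {label!r}")
        basis, value, speeds = GUIDELINE_PRESETS[label]
        for speed in speeds:
            if speed not in profiles:
                raise DataError(f"no profile for speed {speed!r}")
            prof = profiles[speed]
            if basis == "minutes":
                goal_minutes = float(value)
                energy = value / 30.0 * effective_ee_per_30min(prof)
                goal_steps = steps_for_minutes(goal_minutes, prof.cadence)
            else:
                goal_minutes = minutes_for_energy(value, prof)
                energy = float(value)
                goal_steps = steps_for_minutes(
                    minutes_for_energy_unrounded(value, prof), prof.cadence)
            rows.append(RecommendationRow(
                recommendation=label, basis=basis, basis_value=value,
                speed=prof.speed, goal_minutes=goal_minutes,
                goal_steps=goal_steps, energy_kcal=energy,
                cadence=prof.cadence, ree=prof.ree,
                measured_ee=prof.measured_ee,
                additional_ee=additional_daily_ee(prof),
            ))
    return rows
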