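"""Physical constants and study-level configuration tables.

Everything that converts between energy, oxygen uptake and MET lives here so
the simulator, the evaluation metrics and the guideline translation all share
one set of constants.
"""

from __future__ import annotations

from dataclasses import dataclass

#: mL O2 per kg body mass per minute that defines 1 MET (able-bodied convention).
VO2_PER_MET = 3.5

#: Energy equivalent of oxygen, kcal per litre O2 (RER-neutral default).
KCAL_PER_L_O2 = 4.86

#: kcal per MJ, used by REE equations natively expressed in MJ/day.
KCAL_PER_MJ = 239.006

#: Minutes per day, for kcal/min <-> kcal/day conversions.
MIN_PER_DAY = 1440

#: Step-length fraction of body height ("static method"), by sex.
STEP_LENGTH_FRACTION = {"male": 0.415, "female": 0.413}

#: Observed cadence (steps/min) at treadmill-paced walking speeds (km/h).
CADENCE_BY_SPEED = {1: 56, 2: 76, 3: 88, 4: 105, 5: 113, 6: 124}

#: Canonical order of the four activity classes (also the classifier tie-break).
ACTIVITY_CLASSES = ("sedentary", "low_intensity", "high_intensity", "walking")


@dataclass(frozen=True)
class MetConstant:
    """Constants for EE <-> MET conversion."""

    vo2_per_met: float = VO2_PER_MET
    kcal_per_l_o2: float = KCAL_PER_L_O2

    def __post_init__(self) -> None:
        if self.vo2_per_met <= 0 or self.kcal_per_l_o2 <= 0:
            raise ValueError("MET constants must be positive")


def met_to_ee(met: float, weight_kg: float, constants: MetConstant = MetConstant()) -> float:
    """Convert a MET intensity to energy expenditure in kcal/day.

    VO2 [mL/min] = MET * vo2_per_met * weight; EE = VO2 * kcal_per_l_o2 / 1000
    per minute, scaled to a day.
    """
    if weight_kg <= 0:
        raise ValueError("weight must be positive")
    vo2_ml_min = met * constants.vo2_per_met * weight_kg
    return vo2_ml_min / 1000.0 * constants.kcal_per_l_o2 * MIN_PER_DAY


def ee_to_met(ee_kcal_day: float, weight_kg: float, constants: MetConstant = MetConstant()) -> float:
    """Convert energy expenditure in kcal/day to MET (inverse of :func:`met_to_ee`)."""
    if weight_kg <= 0:
        raise ValueError("weight must be positive")
    vo2_ml_min = ee_kcal_day / (MIN_PER_DAY * constants.kcal_per_l_o2) * 1000.0
    return vo2_ml_min / (constants.vo2_per_met * weight_kg)
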