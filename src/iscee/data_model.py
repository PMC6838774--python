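"""Domain types for multi-site wearable recordings and labeled activity windows.

Canonical units throughout: acceleration in g, angular velocity in deg/s,
altitude in m, energy expenditure in kcal/day, time in seconds from session
start.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Mapping, Optional, Sequence

import numpy as np

from .constants import ACTIVITY_CLASSES

SENSOR_SITES = (
    "wrist_L",
    "wrist_R",
    "ankle_L",
    "ankle_R",
    "foot_L",
    "foot_R",
    "chest",
    "hip",
)


class DataError(ValueError):
    """Raised when input data violates a structural invariant."""


class FormatError(ValueError):
    """Raised when an on-disk artifact does not match the expected layout."""


@dataclass
class SensorRecording:
    """One body site's synchronized accel/gyro/altitude streams.

    ``acc`` and ``gyro`` are (n, 3) arrays; ``alt`` is (n,); ``t`` is seconds.
    """

    site: str
    t: np.ndarray
    acc: np.ndarray
    gyro: np.ndarray
    alt: np.ndarray
    fs: float

    def __post_init__(self) -> None:
        if self.site not in SENSOR_SITES:
            raise DataError(f"unknown sensor site {self.site!r}")
        self.t = np.asarray(self.t, dtype=float)
        self.acc = np.asarray(self.acc, dtype=float)
        self.gyro = np.asarray(self.gyro, dtype=float)
        self.alt = np.asarray(self.alt, dtype=float)
        n = self.t.shape[0]
        if self.acc.shape != (n, 3) or self.gyro.shape != (n, 3) or self.alt.shape != (n,):
            raise DataError(
                f"channel length mismatch at site {self.site}: "
                f"t={n}, acc={self.acc.shape}, gyro={self.gyro.shape}, alt={self.alt.shape}"
            )
        if n > 1 and not np.all(np.diff(self.t) > 0):
            raise DataError(f"timestamps not strictly increasing at site {self.site}")
        if self.fs <= 0:
            raise DataError("sampling rate must be positive")

    def __len__(self) -> int:
        return self.t.shape[0]

    def slice_time(self, t0: float, t1: float) -> "SensorRecording":
        """Return the sub-recording on the half-open interval [t0, t1)."""
        mask = (self.t >= t0) & (self.t < t1)
        return SensorRecording(
            site=self.site,
            t=self.t[mask],
            acc=self.acc[mask],
            gyro=self.gyro[mask],
            alt=self.alt[mask],
            fs=self.fs,
        )


@dataclass
class SubjectProfile:
    """Demographics, handedness and clinical scores for one participant."""

    id: str
    age: float
    sex: str
    weight: float  # kg
    height: float  # m
    handedness: str = "right"
    sport_hours_per_week: float = 0.0
    scores: dict = field(default_factory=dict)
    ree_est: Optional[float] = None  # kcal/day
    ree_meas: Optional[float] = None  # kcal/day

    def __post_init__(self) -> None:
        if self.sex not in ("male", "female"):
            raise DataError(f"sex must be 'male' or 'female', got {self.sex!r}")
        if self.handedness not in ("left", "right"):
            raise DataError(f"handedness must be 'left' or 'right', got {self.handedness!r}")
        if self.age < 18:
            raise DataError("participants are adults (age >= 18)")
        if self.weight <= 0 or self.height <= 0:
            raise DataError("weight and height must be positive")
        for name in ("ree_est", "ree_meas"):
            v = getattr(self, name)
            if v is not None and v <= 0:
                raise DataError(f"{name} must be positive when present")

    @property
    def bmi(self) -> float:
        return self.weight / self.height**2

    def dominant_side(self) -> str:
        return "R" if self.handedness == "right" else "L"


@dataclass
class ActivityWindow:
    """One 60-s labeled segment of the session.

    ``signals`` maps site name -> SensorRecording slice. ``ground_truth`` may
    carry simulator sidecar information (step events, true MET, drop reason).
    """

    subject_id: str
    activity_name: str
    activity_class: str
    window_index: int
    signals: Mapping[str, SensorRecording] = field(default_factory=dict)
    ee_meas: Optional[float] = None  # kcal/day
    steady_state: bool = True
    complete: bool = True
    duration: float = 60.0
    ground_truth: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.activity_class not in ACTIVITY_CLASSES:
            raise DataError(f"unknown activity class {self.activity_class!r}")
        if self.ee_meas is not None and self.ee_meas <= 0:
            raise DataError("measured EE must be positive when present")

    def usable_for_fitting(self) -> bool:
        return self.complete and self.steady_state and self.ee_meas is not None


@dataclass
class SessionDataset:
    """A cohort: subjects plus their labeled activity windows."""

    subjects: list
    windows: list

    def __post_init__(self) -> None:
        ids = {s.id for s in self.subjects}
        if len(ids) != len(self.subjects):
            raise DataError("duplicate subject ids")
        for w in self.windows:
            if w.subject_id not in ids:
                raise DataError(f"window references unknown subject {w.subject_id!r}")

    def subject(self, subject_id: str) -> SubjectProfile:
        for s in self.subjects:
            if s.id == subject_id:
                return s
        raise KeyError(subject_id)

    def windows_for(self, subject_id: str) -> list:
        return [w for w in self.windows if w.subject_id == subject_id]

    def __iter__(self) -> Iterator[ActivityWindow]:
        return iter(self.windows)


def resolve_site(code: str, handedness: str) -> str:
    """Map a dominance-relative location code to a concrete sensor site.

    Codes follow the feature-naming convention: DW/NDW (dominant /
    non-dominant wrist), DA/NDA (ankles), DF/NDF (feet), Ch (chest), Hi (hip).
    """
    dom = "R" if handedness == "right" else "L"
    non = "L" if dom == "R" else "R"
    table = {
        "DW": f"wrist_{dom}",
        "NDW": f"wrist_{non}",
        "DA": f"ankle_{dom}",
        "NDA": f"ankle_{non}",
        "DF": f"foot_{dom}",
        "NDF": f"foot_{non}",
        "Ch": "chest",
        "Hi": "hip",
    }
    try:
        return table[code]
    except KeyError:
        raise DataError(f"unknown location code {code!r}") from None
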