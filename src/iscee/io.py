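"""Session readers/writers and stream alignment.

On-disk layout (delimited, diff-able):

    session_dir/
      subjects.csv                  one row per subject
      windows.csv                   one row per window (metadata + labels)
      signals/<sid>_<activity>_w<idx>_<site>.csv   per-site series per window

Numbers are written with 10 significant digits, so read(write(x)) agrees with
x to ~1e-9 relative.
"""

from __future__ import annotations

import json
import os
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .data_model import (
    ActivityWindow,
    DataError,
    FormatError,
    SensorRecording,
    SessionDataset,
    SubjectProfile,
)

_SIGNAL_COLUMNS = ["t", "acc_x", "acc_y", "acc_z", "gyro_x", "gyro_y", "gyro_z", "alt"]
_FLOAT_FMT = "%.10g"


class AlignmentError(ValueError):
    """Raised when streams share no overlapping time support."""


def _subject_row(s: SubjectProfile) -> dict:
    return {
        "id": s.id,
        "age": s.age,
        "sex": s.sex,
        "weight": s.weight,
        "height": s.height,
        "handedness": s.handedness,
        "sport_hours_per_week": s.sport_hours_per_week,
        "scores": json.dumps(s.scores, sort_keys=True),
        "ree_est": "" if s.ree_est is None else s.ree_est,
        "ree_meas": "" if s.ree_meas is None else s.ree_meas,
    }


def write_session(dataset: SessionDataset, path: str | os.PathLike) -> None:
    """Write a dataset to ``path`` (created if absent). Lossless to ~1e-9."""
    root = Path(path)
    sig_dir = root / "signals"
    sig_dir.mkdir(parents=True, exist_ok=True)

    subject_cols = ["id", "age", "sex", "weight", "height", "handedness",
                    "sport_hours_per_week", "scores", "ree_est", "ree_meas"]
    pd.DataFrame([_subject_row(s) for s in dataset.subjects], columns=subject_cols) \
        .to_csv(root / "subjects.csv", index=False, float_format=_FLOAT_FMT)

    wrows = []
    for w in dataset.windows:
        wrows.append({
            "subject_id": w.subject_id,
            "activity_name": w.activity_name,
            "activity_class": w.activity_class,
            "window_index": w.window_index,
            "ee_meas": "" if w.ee_meas is None else w.ee_meas,
            "steady_state": w.steady_state,
            "complete": w.complete,
            "duration": w.duration,
            "sites": ";".join(sorted(w.signals.keys())),
            "ground_truth": json.dumps(w.ground_truth, sort_keys=True, default=list),
        })
        for site, rec in sorted(w.signals.items()):
            arr = np.column_stack([rec.t, rec.acc, rec.gyro, rec.alt])
            df = pd.DataFrame(arr, columns=_SIGNAL_COLUMNS)
            df.attrs["fs"] = rec.fs
            name = f"{w.subject_id}_{w.activity_name}_w{w.window_index}_{site}.csv"
            with open(sig_dir / name, "w") as fh:
                fh.write(f"# fs={rec.fs:.10g}\n")
                df.to_csv(fh, index=False, float_format=_FLOAT_FMT)
    cols = ["subject_id", "activity_name", "activity_class", "window_index",
            "ee_meas", "steady_state", "complete", "duration", "sites", "ground_truth"]
    pd.DataFrame(wrows, columns=cols).to_csv(root / "windows.csv", index=False,
                                             float_format=_FLOAT_FMT)


def _read_signal_file(path: Path, site: str) -> SensorRecording:
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("# fs="):
            raise FormatError(f"{path.name}: missing fs header line")
        fs = float(header.strip().split("=", 1)[1])
        df = pd.read_csv(fh)
    missing = [c for c in _SIGNAL_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path.name} (site {site}): missing channels {missing}")
    t = df["t"].to_numpy()
    if len(t) > 1 and not np.all(np.diff(t) > 0):
        raise DataError(f"{path.name}: non-monotone timestamps")
    return SensorRecording(
        site=site,
        t=t,
        acc=df[["acc_x", "acc_y", "acc_z"]].to_numpy(),
        gyro=df[["gyro_x", "gyro_y", "gyro_z"]].to_numpy(),
        alt=df["alt"].to_numpy(),
        fs=fs,
    )


def read_session(path: str | os.PathLike) -> SessionDataset:
    """Read a dataset written by :func:`write_session`, validating invariants."""
    root = Path(path)
    if not root.exists():
        raise FileNotFoundError(path)
    sdf = pd.read_csv(root / "subjects.csv", dtype={"id": str})
    subjects = []
    for _, r in sdf.iterrows():
        subjects.append(SubjectProfile(
            id=str(r["id"]),
            age=float(r["age"]),
            sex=str(r["sex"]),
            weight=float(r["weight"]),
            height=float(r["height"]),
            handedness=str(r["handedness"]),
            sport_hours_per_week=float(r["sport_hours_per_week"]),
            scores=json.loads(r["scores"]) if isinstance(r["scores"], str) else {},
            ree_est=None if pd.isna(r["ree_est"]) else float(r["ree_est"]),
            ree_meas=None if pd.isna(r["ree_meas"]) else float(r["ree_meas"]),
        ))
    wdf = pd.read_csv(root / "windows.csv", dtype={"subject_id": str})
    windows = []
    for _, r in wdf.iterrows():
        sites = [] if pd.isna(r["sites"]) or r["sites"] == "" else str(r["sites"]).split(";")
        signals = {}
        for site in sites:
            fname = (root / "signals" /
                     f"{r['subject_id']}_{r['activity_name']}_w{int(r['window_index'])}_{site}.csv")
            if not fname.exists():
                raise FormatError(f"missing signal file for site {site}: {fname.name}")
            signals[site] = _read_signal_file(fname, site)
        windows.append(ActivityWindow(
            subject_id=str(r["subject_id"]),
            activity_name=str(r["activity_name"]),
            activity_class=str(r["activity_class"]),
            window_index=int(r["window_index"]),
            signals=signals,
            ee_meas=None if pd.isna(r["ee_meas"]) else float(r["ee_meas"]),
            steady_state=bool(r["steady_state"]),
            complete=bool(r["complete"]),
            duration=float(r["duration"]),
            ground_truth=json.loads(r["ground_truth"]) if isinstance(r["ground_truth"], str) else {},
        ))
    return SessionDataset(subjects=subjects, windows=windows)


def align_streams(recordings: Sequence[SensorRecording], target_fs: float) -> list:
    """Resample all recordings onto one shared timestamp grid at ``target_fs``.

    Linear interpolation on the intersection of time supports; no
    extrapolation beyond any stream's original support.
    """
    if not recordings:
        return []
    t0 = max(r.t[0] for r in recordings)
    t1 = min(r.t[-1] for r in recordings)
    if t1 <= t0:
        raise AlignmentError("recordings have no overlapping time support")
    n = int(np.floor((t1 - t0) * target_fs)) + 1
    grid = t0 + np.arange(n) / target_fs
    out = []
    for r in recordings:
        acc = np.column_stack([np.interp(grid, r.t, r.acc[:, i]) for i in range(3)])
        gyro = np.column_stack([np.interp(grid, r.t, r.gyro[:, i]) for i in range(3)])
        alt = np.interp(grid, r.t, r.alt)
        out.append(SensorRecording(site=r.site, t=grid.copy(), acc=acc, gyro=gyro,
                                   alt=alt, fs=target_fs))
    return out
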