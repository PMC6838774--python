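"""Resting energy expenditure (REE) prediction equations and their evaluation.

Five literature equations are available; the updated Harris-Benedict equation
is the package default, as it gives the lowest mean absolute error for
ambulatory cohorts whose body composition resembles the non-disabled
population. Coefficients are shipped as data (a versioned JSON table with a
provenance string per equation), not code.
"""

from __future__ import annotations

import json
from importlib import resources

import numpy as np
import pandas as pd

from .constants import KCAL_PER_MJ
from .data_model import SubjectProfile

REE_MODELS = ("harris_benedict", "updated_harris_benedict", "mifflin_st_jeor",
              "mueller", "mueller_bmi")
DEFAULT_REE_MODEL = "updated_harris_benedict"


class ReeNotConfiguredError(RuntimeError):
    """The requested equation needs a coefficient table that is not shipped."""


def _load_equations() -> dict:
    with resources.files("iscee.data").joinpath("ree_equations.json").open() as fh:
        return json.load(fh)["equations"]


_EQUATIONS = _load_equations()


def estimate_ree(subject: SubjectProfile, model_id: str = DEFAULT_REE_MODEL,
                 bmi_coefficients: dict | None = None) -> float:
    """Predict resting EE in kcal/day from demographics.

    ``mueller_bmi`` evaluates BMI-class-specific coefficients which are not
    shipped (they live only in the primary source); pass them as
    ``bmi_coefficients`` = {(bmi_lo, bmi_hi): {sex: {...}}} or get an
    explicit not-configured error.
    """
    if model_id not in REE_MODELS:
        raise ValueError(f"unknown REE model {model_id!r}; choose from {REE_MODELS}")
    eq = _EQUATIONS[model_id]
    height_cm = subject.height * 100.0
    if model_id == "mueller_bmi":
        if bmi_coefficients is None:
            raise ReeNotConfiguredError(
                "BMI-dependent Mueller equation requires a user-supplied "
                "coefficient table (transcribe it from the primary source)")
        bmi = subject.bmi
        for (lo, hi), per_sex in bmi_coefficients.items():
            if lo <= bmi < hi:
                c = per_sex[subject.sex]
                val = (c["intercept"] + c["weight"] * subject.weight
                       + c.get("height_cm", 0.0) * height_cm + c["age"] * subject.age)
                return val * KCAL_PER_MJ if eq["unit"] == "MJ/day" else val
        raise ValueError(f"no BMI class covers BMI {bmi:.1f}")
    c = eq[subject.sex]
    val = (c["intercept"] + c["weight"] * subject.weight
           + c["height_cm"] * height_cm + c["age"] * subject.age)
    if eq["unit"] == "MJ/day":
        val *= KCAL_PER_MJ
    return float(val)


def attach_ree_estimates(subjects, model_id: str = DEFAULT_REE_MODEL) -> None:
    """Set ``ree_est`` on each subject in place using the chosen equation."""
    for s in subjects:
        s.ree_est = estimate_ree(s, model_id)


def evaluate_ree_models(subjects, models=None) -> pd.DataFrame:
    """Per-model REE error report against measured REE.

    Returns a frame with MAE %, MAE kcal/day, mean signed error % and
    kcal/day, and max error %, overall and by sex. Subjects without a
    measured REE are excluded; an empty cohort is an error.
    """
    models = list(models) if models is not None else [m for m in REE_MODELS if m != "mueller_bmi"]
    subs = [s for s in subjects if s.ree_meas is not None]
    if not subs:
        raise ValueError("no subjects with measured REE")
    rows = []
    for model in models:
        pred = np.array([estimate_ree(s, model) for s in subs])
        meas = np.array([s.ree_meas for s in subs])
        err = pred - meas
        pct = err / meas * 100.0
        sexes = np.array([s.sex for s in subs])
        row = {
            "model": model,
            "mae_pct": float(np.mean(np.abs(pct))),
            "mae_kcal": float(np.mean(np.abs(err))),
            "mse_pct": float(np.mean(pct)),
            "mse_kcal": float(np.mean(err)),
            "max_err_pct": float(np.max(np.abs(pct))),
            "max_err_kcal": float(np.max(np.abs(err))),
        }
        for sex in ("male", "female"):
            m = sexes == sex
            row[f"mae_pct_{sex}"] = float(np.mean(np.abs(pct[m]))) if m.any() else float("nan")
        rows.append(row)
    return pd.DataFrame(rows).set_index("model")
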