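"""Error metrics, agreement statistics and equivalence testing for EE models.

Percent errors are computed per window against the measured EE; summary MAE
and mean signed error (MSE, in the sense of a signed bias, not a squared
error) are first averaged within subject and then reported as mean ± SD
across subjects, so every participant contributes equally regardless of how
many windows survived gating.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .constants import MIN_PER_DAY, MetConstant


def _check_pairs(measured, predicted):
    m = np.asarray(measured, dtype=float)
    p = np.asarray(predicted, dtype=float)
    if m.shape != p.shape:
        raise ValueError("measured and predicted must have equal length")
    return m, p


def error_metrics(table: pd.DataFrame, by: str | None = None,
                  pool_windows: bool = False) -> pd.DataFrame:
    """Summary EE error metrics from a frame with ee_meas/ee_pred columns.

    Returns one row (or one per subgroup when ``by`` names a column) with MAE
    and mean signed error in percent and kcal/day (mean ± SD across subjects
    unless ``pool_windows``), plus max error, Pearson r and Spearman rho.
    """
    if np.any(table["ee_meas"].to_numpy(dtype=float) <= 0):
        raise ValueError("measured EE must be positive")
    groups = [("overall", table)] if by is None else list(table.groupby(by))
    rows = []
    for name, g in groups:
        if len(g) == 0:
            continue
        meas = g["ee_meas"].to_numpy(dtype=float)
        pred = g["ee_pred"].to_numpy(dtype=float)
        pct = (pred - meas) / meas * 100.0
        kcal = pred - meas
        if pool_windows:
            mae_pct_m, mae_pct_s = float(np.mean(np.abs(pct))), float(np.std(np.abs(pct), ddof=1))
            mse_pct_m, mse_pct_s = float(np.mean(pct)), float(np.std(pct, ddof=1))
            mae_kcal_m = float(np.mean(np.abs(kcal)))
            mse_kcal_m = float(np.mean(kcal))
        else:
            per_subj = g.assign(_pct=pct, _kcal=kcal).groupby("subject_id").agg(
                mae_pct=("_pct", lambda x: np.mean(np.abs(x))),
                mse_pct=("_pct", "mean"),
                mae_kcal=("_kcal", lambda x: np.mean(np.abs(x))),
                mse_kcal=("_kcal", "mean"),
            )
            mae_pct_m = float(per_subj["mae_pct"].mean())
            mae_pct_s = float(per_subj["mae_pct"].std(ddof=1)) if len(per_subj) > 1 else 0.0
            mse_pct_m = float(per_subj["mse_pct"].mean())
            mse_pct_s = float(per_subj["mse_pct"].std(ddof=1)) if len(per_subj) > 1 else 0.0
            mae_kcal_m = float(per_subj["mae_kcal"].mean())
            mse_kcal_m = float(per_subj["mse_kcal"].mean())
        r = pearson(meas, pred) if len(g) >= 3 else float("nan")
        rho = rank_correlation(meas, pred) if len(g) >= 3 else float("nan")
        rows.append({
            "group": name,
            "n_windows": len(g),
            "mae_pct": mae_pct_m, "mae_pct_sd": mae_pct_s,
            "mse_pct": mse_pct_m, "mse_pct_sd": mse_pct_s,
            "mae_kcal": mae_kcal_m, "mse_kcal": mse_kcal_m,
            "max_err_pct": float(np.max(np.abs(pct))),
            "max_err_kcal": float(np.max(np.abs(kcal))),
            "pearson_r": r, "spearman_rho": rho,
        })
    return pd.DataFrame(rows).set_index("group")


@dataclass
class BlandAltman:
    bias: float
    loa_low: float
    loa_high: float
    sd: float


def bland_altman(measured, predicted) -> BlandAltman:
    """Bland-Altman agreement: bias and 95% limits of agreement (±1.96 SD)."""
    m, p = _check_pairs(measured, predicted)
    if m.size < 3:
        raise ValueError("Bland-Altman needs at least 3 pairs")
    d = p - m
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    return BlandAltman(bias=bias, loa_low=bias - 1.96 * sd,
                       loa_high=bias + 1.96 * sd, sd=sd)


@dataclass
class TostResult:
    p_lower: float
    p_upper: float
    equivalent: bool
    zone: float


def equivalence_test(measured, predicted, zone_frac: float = 0.10,
                     alpha: float = 0.05) -> TostResult:
    """Paired TOST: are predictions equivalent to measurements within
    ±zone_frac of the mean measured value?

    Two one-sided paired t-tests of the mean difference against the zone
    bounds; equivalent iff both reject at ``alpha``. With degenerate (zero)
    variance the mean difference is compared to the zone directly.
    """
    m, p = _check_pairs(measured, predicted)
    n = m.size
    if n < 3:
        raise ValueError("equivalence test needs at least 3 pairs")
    d = p - m
    zone = zone_frac * float(np.abs(m.mean()))
    sd = d.std(ddof=1)
    if sd == 0:
        inside = abs(d.mean()) < zone
        return TostResult(p_lower=0.0 if inside else 1.0,
                          p_upper=0.0 if inside else 1.0,
                          equivalent=bool(inside), zone=zone)
    se = sd / np.sqrt(n)
    t_lower = (d.mean() + zone) / se           # H0: mean diff <= -zone
    t_upper = (d.mean() - zone) / se           # H0: mean diff >= +zone
    p_lower = float(stats.t.sf(t_lower, df=n - 1))
    p_upper = float(stats.t.cdf(t_upper, df=n - 1))
    return TostResult(p_lower=p_lower, p_upper=p_upper,
                      equivalent=bool(p_lower < alpha and p_upper < alpha),
                      zone=zone)


def met_from_ee(ee_kcal_day: float, weight_kg: float,
                constants: MetConstant = MetConstant()) -> float:
    """MET intensity of an EE rate given body weight.

    VO2 [mL/min] = EE / (1440 · kcal per L O2) · 1000; MET = VO2 / (3.5 · kg).
    """
    if weight_kg <= 0:
        raise ValueError("weight must be positive")
    vo2_ml_min = ee_kcal_day / (MIN_PER_DAY * constants.kcal_per_l_o2) * 1000.0
    return float(vo2_ml_min / (constants.vo2_per_met * weight_kg))


def pearson(x, y) -> float:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3:
        raise ValueError("need at least 3 pairs")
    if np.std(x) == 0 or np.std(y) == 0:
        return float("nan")
    return float(stats.pearsonr(x, y).statistic)


def rank_correlation(x, y) -> float:
    """Spearman rank correlation with mid-ranked ties; NaN for constant input."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3:
        raise ValueError("need at least 3 pairs")
    if np.std(x) == 0 or np.std(y) == 0:
        return float("nan")
    return float(stats.spearmanr(x, y).statistic)
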