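"""Linear year trends of fitted parameters and the significance-gated forecast.

Each fitted parameter series (MAP, A, E, K, n per sex) is regressed on the
calendar year by ordinary least squares.  Residual diagnostics follow the
standard regression checklist: Durbin-Watson for independence (rule of thumb:
1-3 acceptable), Shapiro-Wilk for normality and Breusch-Pagan for
homoscedasticity.  Diagnostics are reported, never used to drop data.

The forecast rule: the target-year (default 2024) value of a parameter is the
extrapolated regression line when the year relationship is significant
(Pearson p <= alpha, two-sided), and the plain mean of the series otherwise.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.diagnostic import het_breuschpagan

__all__ = ["TrendFit", "durbin_watson", "regress_trend"]

logger = logging.getLogger(__name__)

#: Durbin-Watson rule-of-thumb band for "residuals independent".
DW_BAND = (1.0, 3.0)


@dataclass(frozen=True)
class TrendFit:
    """OLS year trend of one parameter with diagnostics and the forecast."""

    parameter: str
    slope: float  # per year
    intercept: float  # raw-calendar-year parameterisation
    pearson_r: float
    p_value: float
    dw_stat: float
    sw_p: float
    bp_p: float
    prediction_2024: float
    prediction_mode: str  # "extrapolated" or "mean"
    dw_independent: bool = True

    def __post_init__(self) -> None:
        if not (np.isnan(self.pearson_r) or -1.0 <= self.pearson_r <= 1.0 + 1e-12):
            raise ValueError(f"pearson_r out of [-1, 1]: {self.pearson_r}")
        if self.prediction_mode not in ("extrapolated", "mean"):
            raise ValueError(f"bad prediction_mode {self.prediction_mode!r}")


def durbin_watson(residuals: Sequence[float]) -> float:
    """Durbin-Watson statistic sum((e_i - e_{i-1})^2) / sum(e_i^2).

    Near 2 for uncorrelated residuals, near 0 for strong positive
    autocorrelation, near 4 for strong negative autocorrelation.

    Raises
    ------
    ValueError
        For fewer than 3 residuals or an all-zero residual vector (the
        statistic is then undefined).
    """
    e = np.asarray(residuals, dtype=float)
    if e.size < 3:
        raise ValueError(f"need at least 3 residuals, got {e.size}")
    denom = float(np.sum(e * e))
    if denom == 0.0:
        raise ValueError("Durbin-Watson statistic undefined for all-zero residuals")
    return float(np.sum(np.diff(e) ** 2) / denom)


def regress_trend(
    years: Sequence[float],
    values: Sequence[float],
    parameter: str = "",
    alpha: float = 0.05,
    target_year: int = 2024,
) -> TrendFit:
    """OLS fit of a parameter series on calendar year, with the forecast gate.

    Years are centred internally for conditioning; the reported slope and
    intercept are on the raw calendar-year scale.  A constant series (or any
    series where the correlation p-value is undefined) is treated as
    non-significant, so its forecast is the series mean.
    """
    yr = np.asarray(years, dtype=float)
    val = np.asarray(values, dtype=float)
    if yr.size != val.size:
        raise ValueError("years and values must have equal length")
    if yr.size < 3:
        raise ValueError(f"need at least 3 points, got {yr.size}")
    if np.any(np.diff(yr) <= 0):
        raise ValueError("years must be strictly increasing")

    yc = yr - yr.mean()
    sxx = float(np.sum(yc * yc))
    slope = float(np.sum(yc * (val - val.mean())) / sxx)
    intercept = float(val.mean() - slope * yr.mean())
    residuals = val - (intercept + slope * yr)

    if np.std(val) == 0.0:
        r, p = np.nan, np.nan
    else:
        r, p = stats.pearsonr(yr, val)
        r, p = float(r), float(p)

    try:
        dw = durbin_watson(residuals)
    except ValueError:
        dw = np.nan  # exact fit: residuals all ~zero
    sw_p = float(stats.shapiro(residuals).pvalue) if np.ptp(residuals) > 0 else np.nan
    if np.ptp(residuals) > 0:
        exog = np.column_stack([np.ones_like(yr), yr])
        bp_p = float(het_breuschpagan(residuals, exog)[1])
    else:
        bp_p = np.nan

    significant = (not np.isnan(p)) and p <= alpha
    if significant:
        prediction = intercept + slope * target_year
        mode = "extrapolated"
    else:
        prediction = float(val.mean())
        mode = "mean"
    dw_ok = bool(np.isnan(dw) or DW_BAND[0] <= dw <= DW_BAND[1])
    if not dw_ok:
        logger.warning(
            "%s: Durbin-Watson %.2f outside %s; residuals may be autocorrelated",
            parameter or "series", dw, DW_BAND,
        )
    logger.info(
        "%s: slope=%.4g/yr, r=%.3f, p=%.3g -> %s forecast %.6g for %d",
        parameter or "series", slope, r, p, mode, prediction, target_year,
    )
    return TrendFit(
        parameter=parameter,
        slope=slope,
        intercept=intercept,
        pearson_r=r,
        p_value=p,
        dw_stat=float(dw),
        sw_p=sw_p,
        bp_p=bp_p,
        prediction_2024=float(prediction),
        prediction_mode=mode,
        dw_independent=dw_ok,
    )
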