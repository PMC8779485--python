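"""Validation and engine-comparison statistics.

Prediction accuracy is summarized by mean error (bias) and mean absolute
percent error (precision):

    ME   = sum(Cpred_i - Cobs_i) / n
    MAPE = 100 * sum(|Cpred_i - Cobs_i| / Cobs_i) / n

Engine agreement is assessed with rank tests (Wilcoxon signed-rank for
paired quantities, Mann-Whitney for independent ones; exact for n <= 25,
normal approximation with continuity correction beyond), the coefficient of
determination between engines, and Bland-Altman analysis.  When the
regression of differences on averages has a slope significantly different
from zero (proportional bias), regression-based limits of agreement replace
the classic mean +/- 1.96 SD bands.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .dosing import ExposureTargets
from .pk import InvalidParameterError

__all__ = [
    "PredictionPairs",
    "BlandAltmanResult",
    "AttainmentResult",
    "mean_error",
    "mape",
    "bland_altman",
    "compare_engines",
    "target_attainment",
]

_EXACT_N_MAX = 25


@dataclass(frozen=True)
class PredictionPairs:
    """Aligned predicted/observed concentrations (mg/L).

    ``n_excluded_lloq`` records observations dropped because they were
    below the limit of quantification (no point value for the MAPE
    denominator).
    """

    pred: np.ndarray
    obs: np.ndarray
    n_excluded_lloq: int = 0

    def __post_init__(self) -> None:
        p = np.asarray(self.pred, dtype=float)
        o = np.asarray(self.obs, dtype=float)
        if p.shape != o.shape or p.ndim != 1:
            raise InvalidParameterError("pred and obs must be aligned 1-D arrays")
        object.__setattr__(self, "pred", p)
        object.__setattr__(self, "obs", o)

    @property
    def n(self) -> int:
        return self.pred.size


def mean_error(p: PredictionPairs) -> float:
    """Mean prediction error (mg/L); negative means underprediction."""
    if p.n == 0:
        raise InvalidParameterError("mean_error requires at least one pair")
    return float(np.mean(p.pred - p.obs))


def mape(p: PredictionPairs) -> float:
    """Mean absolute percent error, in percent of the observed value."""
    if p.n == 0:
        raise InvalidParameterError("mape requires at least one pair")
    if np.any(p.obs <= 0):
        raise InvalidParameterError("mape is undefined for non-positive observations")
    return float(100.0 * np.mean(np.abs(p.pred - p.obs) / p.obs))


@dataclass(frozen=True)
class BlandAltmanResult:
    """Agreement between two sets of estimates of the same quantity.

    ``mode`` is "classic" (mean difference +/- 1.96 SD) or "regression"
    (fitted difference-vs-average line +/- 1.96 residual SD, used when the
    slope is significant — proportional bias).
    """

    n: int
    mean_difference: float
    sd_difference: float
    loa_lower: float
    loa_upper: float
    slope: float | None
    intercept: float | None
    slope_p: float | None
    residual_sd: float | None
    mode: str

    def bands(self, averages: Sequence[float]) -> pd.DataFrame:
        """Lower/center/upper agreement bands evaluated at given averages."""
        a = np.asarray(averages, dtype=float)
        if self.mode == "regression":
            center = self.intercept + self.slope * a
            half = 1.96 * self.residual_sd
        else:
            center = np.full_like(a, self.mean_difference)
            half = 1.96 * self.sd_difference
        return pd.DataFrame(
            {"average": a, "lower": center - half, "center": center, "upper": center + half}
        )


def bland_altman(x, y, alpha: float = 0.05) -> BlandAltmanResult:
    """Bland-Altman analysis of differences d = x - y against averages."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 3:
        raise InvalidParameterError("bland_altman requires aligned 1-D arrays with n >= 3")
    d = x - y
    a = 0.5 * (x + y)
    mean_d = float(d.mean())
    sd_d = float(d.std(ddof=1))
    slope = intercept = slope_p = resid_sd = None
    mode = "classic"
    if np.ptp(a) > 0:
        fit = stats.linregress(a, d)
        slope, intercept, slope_p = float(fit.slope), float(fit.intercept), float(fit.pvalue)
        resid = d - (intercept + slope * a)
        resid_sd = float(resid.std(ddof=2))
        if slope_p < alpha:
            mode = "regression"
    return BlandAltmanResult(
        n=x.size,
        mean_difference=mean_d,
        sd_difference=sd_d,
        loa_lower=mean_d - 1.96 * sd_d,
        loa_upper=mean_d + 1.96 * sd_d,
        slope=slope,
        intercept=intercept,
        slope_p=slope_p,
        residual_sd=resid_sd,
        mode=mode,
    )


def _rank_test_p(x: np.ndarray, y: np.ndarray, paired: bool) -> tuple[float, str]:
    """Two-sided rank-test p-value; exact when n permits, else normal
    approximation with continuity correction.  Returns (p, note)."""
    if paired:
        d = x - y
        if np.all(d == 0):
            return math.nan, "undefined: all paired differences are zero"
        method = "exact" if d.size <= _EXACT_N_MAX else "approx"
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = stats.wilcoxon(x, y, correction=(method == "approx"), method=method)
        except ValueError:
            res = stats.wilcoxon(x, y, correction=True, method="approx")
        return float(res.pvalue), "wilcoxon signed-rank"
    method = "exact" if max(x.size, y.size) <= _EXACT_N_MAX else "asymptotic"
    try:
        res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    except ValueError:
        res = stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
    return float(res.pvalue), "mann-whitney"


def compare_engines(
    quantities: Mapping[str, tuple[Sequence[float], Sequence[float]]],
    paired: Sequence[str] = (),
) -> pd.DataFrame:
    """Per-quantity comparison report of two engines' estimates.

    ``quantities`` maps a name (e.g. "auc24") to the aligned (engine A,
    engine B) estimate arrays; names in ``paired`` use the Wilcoxon
    signed-rank test, the rest Mann-Whitney.  Returns one row per quantity:
    mean/SD per engine, p-value, test name, and the R^2 between engines.
    """
    rows = []
    for name, (x, y) in quantities.items():
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        if x.shape != y.shape or x.size < 3:
            raise InvalidParameterError(f"{name}: need aligned arrays with n >= 3")
        p, note = _rank_test_p(x, y, paired=name in paired)
        if x.std() > 0 and y.std() > 0:
            r2 = float(np.corrcoef(x, y)[0, 1] ** 2)
        else:
            r2 = math.nan
        rows.append(
            {
                "quantity": name,
                "n": x.size,
                "engine_a_mean": float(x.mean()),
                "engine_a_sd": float(x.std(ddof=1)),
                "engine_b_mean": float(y.mean()),
                "engine_b_sd": float(y.std(ddof=1)),
                "test": note,
                "p_value": p,
                "r_squared": r2,
            }
        )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class AttainmentResult:
    """Fractions of a cohort outside the exposure targets (strict inequalities)."""

    n: int
    frac_underexposed: float  # AUC24 < auc_target
    frac_overexposed: float  # Cmin > cmin_limit


def target_attainment(
    auc24: Sequence[float],
    cmin: Sequence[float],
    targets: ExposureTargets = ExposureTargets(),
) -> AttainmentResult:
    """Cohort fractions with AUC24 strictly below the efficacy target and
    trough strictly above the safety limit."""
    auc = np.asarray(auc24, dtype=float)
    cm = np.asarray(cmin, dtype=float)
    if auc.size < 1 or auc.shape != cm.shape:
        raise InvalidParameterError("need >= 1 patient with aligned AUC and Cmin")
    return AttainmentResult(
        n=auc.size,
        frac_underexposed=float(np.mean(auc < targets.auc_target)),
        frac_overexposed=float(np.mean(cm > targets.cmin_limit)),
    )
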