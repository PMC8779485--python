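"""AUC- and trough-targeted dose computation from an individual Bayesian fit.

Two daily doses are reported per patient:

* ``Dmin`` — the minimum effective dose attaining the efficacy target
  AUC24 = 666 mg.h/L at steady state (bactericidal threshold for
  S. aureus at MIC 1 mg/L);
* ``Dmax`` — the maximum dose keeping the steady-state trough at the
  muscular-toxicity bound Cmin = 24.3 mg/L.

Because the kinetics are linear, each support point's steady-state AUC24
and Cmin are exactly proportional to the daily dose; the per-mg/day
sensitivities (``s_auc = 1/CL`` exactly, and ``s_cmin``) reduce dose
selection to a one-dimensional problem.  Two objectives are offered:

* ``expectation`` — hit the target in posterior expectation, D = T / E[s];
* ``mm_squared_error`` (default) — minimize the posterior-expected squared
  deviation from the target, D = T * E[s] / E[s^2], the multiple-model
  dosage-design objective.  For a one-point posterior (the MAP engine)
  both coincide at D = T / s.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .bayes import MapEstimate, PosteriorWeights
from .pk import DosingRegimen, InvalidParameterError, steady_state_metrics_arrays

__all__ = [
    "ExposureTargets",
    "DoseRecommendation",
    "UnitDoseResponse",
    "unit_dose_response",
    "compute_dmin",
    "compute_dmax",
    "recommend_doses",
]

MODES = ("expectation", "mm_squared_error")


@dataclass(frozen=True)
class ExposureTargets:
    """PK/PD targets: efficacy AUC24 (mg.h/L) and safety trough (mg/L)."""

    auc_target: float = 666.0
    cmin_limit: float = 24.3

    def __post_init__(self) -> None:
        if not (math.isfinite(self.auc_target) and self.auc_target > 0):
            raise InvalidParameterError("auc_target must be > 0")
        if not (math.isfinite(self.cmin_limit) and self.cmin_limit > 0):
            raise InvalidParameterError("cmin_limit must be > 0")


@dataclass(frozen=True)
class DoseRecommendation:
    """Continuous daily doses plus practical (10 mg-rounded) equivalents.

    ``dmin_*`` or ``dmax_*`` may be None when only one target was computed.
    """

    objective_mode: str
    weight_kg: float
    dmin_mg_day: float | None = None
    dmax_mg_day: float | None = None

    @property
    def dmin_mg_kg(self) -> float | None:
        return None if self.dmin_mg_day is None else self.dmin_mg_day / self.weight_kg

    @property
    def dmax_mg_kg(self) -> float | None:
        return None if self.dmax_mg_day is None else self.dmax_mg_day / self.weight_kg

    @property
    def dmin_practical_mg(self) -> float | None:
        return None if self.dmin_mg_day is None else round(self.dmin_mg_day / 10.0) * 10.0

    @property
    def dmax_practical_mg(self) -> float | None:
        return None if self.dmax_mg_day is None else round(self.dmax_mg_day / 10.0) * 10.0


@dataclass(frozen=True)
class UnitDoseResponse:
    """Per-support steady-state response to 1 mg/day on the template schedule."""

    s_auc: np.ndarray  # (mg.h/L) per (mg/day); equals 1/CL
    s_cmin: np.ndarray  # (mg/L) per (mg/day)
    weights: np.ndarray


def unit_dose_response(
    fit: PosteriorWeights | MapEstimate, template: DosingRegimen
) -> UnitDoseResponse:
    """Steady-state AUC24 and Cmin per 1 mg/day, per posterior support point.

    The template fixes the dosing interval and infusion duration; the dose
    per administration for 1 mg/day is interval/24 mg.
    """
    ev = template.maintenance_dose
    dose_per_admin = template.interval_h / 24.0  # mg, for a 1 mg/day rate
    if isinstance(fit, MapEstimate):
        r = fit.resolved
        v1, ke, kcp, kpc = (
            np.array([r.v1_abs]),
            np.array([r.ke]),
            np.array([r.kcp]),
            np.array([r.kpc]),
        )
        weights = np.array([1.0])
    else:
        v1, ke, kcp, kpc = fit.resolved_arrays()
        weights = fit.weights
    auc24, cmin, _cmax, _th, _cl = steady_state_metrics_arrays(
        v1, ke, kcp, kpc, dose_per_admin, template.interval_h, ev.infusion_duration_h
    )
    return UnitDoseResponse(s_auc=auc24, s_cmin=cmin, weights=weights)


def _target_dose(s: np.ndarray, w: np.ndarray, target: float, mode: str) -> float:
    if mode not in MODES:
        raise InvalidParameterError(f"objective_mode must be one of {MODES}")
    es = float(w @ s)
    if es <= 0 or not math.isfinite(es):
        raise InvalidParameterError("degenerate (zero) posterior dose sensitivity")
    if mode == "expectation":
        return target / es
    es2 = float(w @ (s * s))
    return target * es / es2


def compute_dmin(
    fit: PosteriorWeights | MapEstimate,
    template: DosingRegimen,
    targets: ExposureTargets = ExposureTargets(),
    mode: str = "mm_squared_error",
) -> DoseRecommendation:
    """Daily dose targeting AUC24 = ``targets.auc_target`` at steady state."""
    udr = unit_dose_response(fit, template)
    d = _target_dose(udr.s_auc, udr.weights, targets.auc_target, mode)
    return DoseRecommendation(
        objective_mode=mode, weight_kg=fit.covariates.weight_kg, dmin_mg_day=d
    )


def compute_dmax(
    fit: PosteriorWeights | MapEstimate,
    template: DosingRegimen,
    targets: ExposureTargets = ExposureTargets(),
    mode: str = "mm_squared_error",
) -> DoseRecommendation:
    """Daily dose putting the steady-state trough at ``targets.cmin_limit``."""
    udr = unit_dose_response(fit, template)
    d = _target_dose(udr.s_cmin, udr.weights, targets.cmin_limit, mode)
    return DoseRecommendation(
        objective_mode=mode, weight_kg=fit.covariates.weight_kg, dmax_mg_day=d
    )


def recommend_doses(
    fit: PosteriorWeights | MapEstimate,
    template: DosingRegimen,
    targets: ExposureTargets = ExposureTargets(),
    mode: str = "mm_squared_error",
) -> DoseRecommendation:
    """Both targets in one recommendation."""
    udr = unit_dose_response(fit, template)
    dmin = _target_dose(udr.s_auc, udr.weights, targets.auc_target, mode)
    dmax = _target_dose(udr.s_cmin, udr.weights, targets.cmin_limit, mode)
    return DoseRecommendation(
        objective_mode=mode,
        weight_kg=fit.covariates.weight_kg,
        dmin_mg_day=dmin,
        dmax_mg_day=dmax,
    )
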