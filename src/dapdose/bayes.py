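"""Individual Bayesian estimation from sparse TDM data.

Two engines share a Gaussian residual likelihood built on the assay error
model (SD evaluated at the *predicted* concentration; observations below
the LLOQ contribute the left-tail probability, i.e. M3-style censoring):

* :func:`np_posterior` — the nonparametric engine.  The discrete prior's
  support points are reweighted by each patient's data likelihood; the
  entire discrete posterior is retained and used downstream for prediction,
  exposure and dosing.
* :func:`map_fit` — the parametric engine.  A single maximum a posteriori
  (MAP) parameter vector is found by penalized optimization on the log
  scale, the penalty being the log-normal population prior around the
  covariate-adjusted typical values.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import approx_fprime, minimize
from scipy.stats import norm

from .pk import (
    Covariates,
    DosingRegimen,
    ExposureMetrics,
    InvalidParameterError,
    ResolvedPK,
    _conc_grid,
    predict_concentrations,
    resolve_support,
    steady_state_metrics,
    steady_state_metrics_arrays,
)
from .priors import (
    AssayErrorModel,
    NonparametricPrior,
    ParametricPrior,
    macro_to_micro,
)

__all__ = [
    "ObservationSet",
    "PosteriorWeights",
    "MapEstimate",
    "DegeneratePosteriorError",
    "MapFitError",
    "log_likelihood",
    "np_posterior",
    "map_fit",
    "posterior_predict",
    "posterior_exposure",
    "PosteriorExposure",
]

_LOG_SQRT_2PI = 0.5 * math.log(2.0 * math.pi)


class DegeneratePosteriorError(RuntimeError):
    """Every support point has zero likelihood to machine precision."""


class MapFitError(RuntimeError):
    """MAP optimization failed to converge; carries the best point found."""

    def __init__(self, message: str, best: "MapEstimate | None" = None):
        super().__init__(message)
        self.best = best


@dataclass(frozen=True)
class ObservationSet:
    """Timed concentrations for one patient, tied to covariates and doses.

    ``below_lloq`` flags left-censored observations; flagged values are
    treated as "concentration < LLOQ" regardless of the stored number.
    """

    times_h: np.ndarray
    conc_mg_l: np.ndarray
    below_lloq: np.ndarray
    covariates: Covariates
    regimen: DosingRegimen

    def __post_init__(self) -> None:
        t = np.asarray(self.times_h, dtype=float)
        c = np.asarray(self.conc_mg_l, dtype=float)
        b = np.asarray(self.below_lloq, dtype=bool)
        if not (t.shape == c.shape == b.shape) or t.ndim != 1:
            raise InvalidParameterError("times, concentrations and flags must be aligned 1-D")
        if np.any(c < 0):
            raise InvalidParameterError("concentrations must be >= 0")
        if t.size and (t.min() < 0 or t.max() > self.regimen.span_h + self.regimen.interval_h):
            raise InvalidParameterError(
                "observation times must lie within the dosing history span plus one interval"
            )
        object.__setattr__(self, "times_h", t)
        object.__setattr__(self, "conc_mg_l", c)
        object.__setattr__(self, "below_lloq", b)

    @property
    def n(self) -> int:
        return self.times_h.size

    @classmethod
    def empty(cls, covariates: Covariates, regimen: DosingRegimen) -> "ObservationSet":
        z = np.zeros(0)
        return cls(z, z.copy(), z.astype(bool), covariates, regimen)


@dataclass(frozen=True)
class PosteriorWeights:
    """Discrete posterior: the prior's support with updated masses."""

    support: np.ndarray
    weights: np.ndarray
    covariates: Covariates
    regimen: DosingRegimen

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if np.any(w < 0) or abs(w.sum() - 1.0) > 1e-12:
            raise InvalidParameterError("posterior weights must be >= 0 and sum to 1")
        object.__setattr__(self, "weights", w)
        object.__setattr__(self, "support", np.asarray(self.support, dtype=float))

    @property
    def n_support(self) -> int:
        return self.support.shape[0]

    def resolved_arrays(self) -> tuple[np.ndarray, ...]:
        return resolve_support(self.support, self.covariates)


@dataclass(frozen=True)
class MapEstimate:
    """MAP point estimate on the clearance parameterization."""

    resolved: ResolvedPK
    theta: np.ndarray  # (CL, V1, Q, V2)
    objective: float
    gradient_norm: float
    covariates: Covariates
    regimen: DosingRegimen


# ---------------------------------------------------------------------------
# likelihood
# ---------------------------------------------------------------------------


def _loglik_rows(pred: np.ndarray, obs: ObservationSet, e: AssayErrorModel) -> np.ndarray:
    """Row-wise Gaussian/censored log-likelihood for predictions (N, n_obs)."""
    sd = e.sd(pred)
    with np.errstate(divide="ignore", invalid="ignore", over="ignore"):
        z = (obs.conc_mg_l[None, :] - pred) / sd
        ll = -0.5 * z * z - np.log(sd) - _LOG_SQRT_2PI
        cens = norm.logcdf((e.lloq - pred) / sd)
    ll = np.where(obs.below_lloq[None, :], cens, ll)
    ll = np.where(sd > 0, ll, -np.inf)
    return ll.sum(axis=1)


def log_likelihood(r: ResolvedPK, obs: ObservationSet, e: AssayErrorModel) -> float:
    """Gaussian log-likelihood of the observations given resolved parameters.

    Residual SD is the assay polynomial evaluated at the predicted
    concentration; below-LLOQ observations contribute log P(C < LLOQ).
    """
    if obs.n == 0:
        return 0.0
    pred = predict_concentrations(r, obs.regimen, obs.times_h)
    return float(_loglik_rows(pred[None, :], obs, e)[0])


# ---------------------------------------------------------------------------
# nonparametric engine
# ---------------------------------------------------------------------------


def np_posterior(
    prior: NonparametricPrior, obs: ObservationSet, e: AssayErrorModel
) -> PosteriorWeights:
    """Reweight the discrete prior by the patient's likelihood.

    Computed in log space with max-subtraction; an empty observation set
    returns the prior weights unchanged.
    """
    if obs.n == 0:
        return PosteriorWeights(prior.support, prior.weights, obs.covariates, obs.regimen)
    v1, ke, kcp, kpc = resolve_support(prior.support, obs.covariates)
    pred = _conc_grid(v1, ke, kcp, kpc, obs.regimen.dose_events, obs.times_h)
    loglik = _loglik_rows(pred, obs, e)
    with np.errstate(divide="ignore"):
        logw = np.log(prior.weights) + loglik
    finite = np.isfinite(logw)
    if not np.any(finite):
        raise DegeneratePosteriorError(
            "all support points have zero likelihood; check units, dosing history "
            f"and assay error model (best log-likelihood {loglik.max():.1f})"
        )
    w = np.exp(logw - logw[finite].max())
    w[~finite] = 0.0
    w = w / w.sum()
    return PosteriorWeights(prior.support, w, obs.covariates, obs.regimen)


# ---------------------------------------------------------------------------
# parametric (MAP) engine
# ---------------------------------------------------------------------------


def _map_objective(eta: np.ndarray, typicals_log, free, omegas, obs, e) -> float:
    full = np.zeros(4)
    full[free] = eta
    theta = np.exp(typicals_log + full)
    cl, v1, q, v2 = theta
    r = ResolvedPK(v1_abs=v1, ke=cl / v1, kcp=q / v1, kpc=q / v2)
    penalty = 0.5 * np.sum((full[free] / omegas[free]) ** 2)
    return penalty - log_likelihood(r, obs, e)


def map_fit(
    prior: ParametricPrior,
    obs: ObservationSet,
    e: AssayErrorModel,
    grad_tol: float = 1e-2,
) -> MapEstimate:
    """Maximum a posteriori fit of (CL, V1, Q, V2) on the log scale.

    The objective is -log-likelihood plus the log-normal prior penalty
    around covariate-adjusted typical values.  Optimization runs L-BFGS-B
    from a fixed multi-start schedule (prior mode, all parameters shifted
    by +/-1 prior SD, CL alone shifted by +/-1 SD), so the result is
    deterministic.  With no observations the prior mode is returned exactly.
    """
    typicals = prior.covariate_typicals(obs.covariates)
    typicals_log = np.log(typicals)
    omegas = prior.omegas
    free = omegas > 0

    if obs.n == 0 or not np.any(free):
        r = macro_to_micro(*typicals)
        return MapEstimate(
            resolved=r,
            theta=typicals,
            objective=_map_objective(np.zeros(int(free.sum())), typicals_log, free, omegas, obs, e),
            gradient_norm=0.0,
            covariates=obs.covariates,
            regimen=obs.regimen,
        )

    n_free = int(free.sum())
    om = omegas[free]
    starts = [np.zeros(n_free), om.copy(), -om.copy()]
    e0 = np.zeros(n_free)
    e0[0] = om[0]
    starts += [e0, -e0]

    best = None
    for x0 in starts:
        res = minimize(
            _map_objective,
            x0,
            args=(typicals_log, free, omegas, obs, e),
            method="L-BFGS-B",
            options={"maxiter": 500, "ftol": 1e-12, "gtol": 1e-8},
        )
        if best is None or res.fun < best.fun:
            best = res

    grad = approx_fprime(best.x, _map_objective, 1e-7, typicals_log, free, omegas, obs, e)
    full = np.zeros(4)
    full[free] = best.x
    theta = np.exp(typicals_log + full)
    estimate = MapEstimate(
        resolved=macro_to_micro(*theta),
        theta=theta,
        objective=float(best.fun),
        gradient_norm=float(np.linalg.norm(grad)),
        covariates=obs.covariates,
        regimen=obs.regimen,
    )
    if not np.isfinite(best.fun) or np.linalg.norm(grad) > grad_tol * max(1.0, abs(best.fun)):
        raise MapFitError(
            f"MAP optimization did not converge (objective {best.fun:.6g}, "
            f"|grad| {np.linalg.norm(grad):.3g}); best point attached",
            best=estimate,
        )
    return estimate


# ---------------------------------------------------------------------------
# posterior predictions and exposure
# ---------------------------------------------------------------------------


def posterior_predict(
    fit: PosteriorWeights | MapEstimate, times: Iterable[float]
) -> np.ndarray:
    """Predicted concentrations: posterior-weighted mean (NP) or the MAP
    point prediction (parametric)."""
    times = np.asarray(list(times) if not isinstance(times, np.ndarray) else times, float)
    if isinstance(fit, MapEstimate):
        return predict_concentrations(fit.resolved, fit.regimen, times)
    v1, ke, kcp, kpc = fit.resolved_arrays()
    pred = _conc_grid(v1, ke, kcp, kpc, fit.regimen.dose_events, times)
    return fit.weights @ pred


@dataclass(frozen=True)
class PosteriorExposure:
    """Expected steady-state exposure plus, for the NP engine, the full
    per-support-point table (columns: weight, auc24, cmin, cmax, t_half, cl)."""

    metrics: ExposureMetrics
    per_support: pd.DataFrame | None = None


def posterior_exposure(
    fit: PosteriorWeights | MapEstimate, reg: DosingRegimen | None = None
) -> PosteriorExposure:
    """Steady-state exposure under the fit, for the regimen ``reg`` (default:
    the fitted patient's own regimen)."""
    reg = reg if reg is not None else fit.regimen
    ev = reg.maintenance_dose
    if isinstance(fit, MapEstimate):
        return PosteriorExposure(metrics=steady_state_metrics(fit.resolved, reg))
    v1, ke, kcp, kpc = fit.resolved_arrays()
    auc24, cmin, cmax, t_half, cl = steady_state_metrics_arrays(
        v1, ke, kcp, kpc, ev.dose_mg, reg.interval_h, ev.infusion_duration_h
    )
    table = pd.DataFrame(
        {
            "weight": fit.weights,
            "auc24_ss": auc24,
            "cmin_ss": cmin,
            "cmax_ss": cmax,
            "t_half_terminal": t_half,
            "cl": cl,
        }
    )
    w = fit.weights
    metrics = ExposureMetrics(
        auc24_ss=float(w @ auc24),
        cmin_ss=float(w @ cmin),
        cmax_ss=float(w @ cmax),
        t_half_terminal=float(w @ t_half),
        cl=float(w @ cl),
    )
    return PosteriorExposure(metrics=metrics, per_support=table)
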