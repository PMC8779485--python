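"""Two-compartment IV-infusion pharmacokinetics of daptomycin.

The disposition model is the standard linear two-compartment system driven
by a zero-order (constant-rate) infusion into the central compartment:

    dX1/dt = R(t) - (Ke + Kcp) * X1 + Kpc * X2
    dX2/dt = Kcp * X1 - Kpc * X2,          C(t) = X1 / V1

parameterized with micro rate constants.  Elimination is split into a renal
component scaled by creatinine clearance and a non-renal component,

    Ke = Ks * (CLcr / 100) + Ki,

and the central volume is expressed per 70 kg of body weight and scales
linearly with weight (V1 = V1_std * WT / 70).

Concentrations are computed in closed form from the eigenvalues of the
disposition matrix, with superposition over dose events; steady state uses
the geometric accumulation of the exponential terms rather than simulating
many doses.  :func:`ode_oracle` provides an independent stiff-safe numerical
integrator for testing.

Units: time in hours (t = 0 at first dose start), amounts in mg, volumes in
L, concentrations in mg/L, rate constants in 1/h.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy.integrate import solve_ivp

__all__ = [
    "PKMicroParams",
    "Covariates",
    "ResolvedPK",
    "DoseEvent",
    "DosingRegimen",
    "ExposureMetrics",
    "InvalidParameterError",
    "OracleError",
    "resolve_parameters",
    "predict_concentrations",
    "steady_state_metrics",
    "terminal_half_life",
    "ode_oracle",
]

PARAM_NAMES = ("v1_std", "ks", "ki", "kcp", "kpc")

#: relative discriminant size below which the two disposition eigenvalues are
#: treated as confluent and the analytic degenerate limit is used
_DEGENERATE_RTOL = 1e-10


class InvalidParameterError(ValueError):
    """A pharmacokinetic parameter or derived quantity is non-positive or non-finite."""


class OracleError(RuntimeError):
    """The reference numerical integrator failed to converge."""


def _require_positive_finite(**kwargs: float) -> None:
    for name, value in kwargs.items():
        if not (math.isfinite(value) and value > 0):
            raise InvalidParameterError(f"{name} must be positive and finite, got {value!r}")


@dataclass(frozen=True)
class PKMicroParams:
    """Micro-constant parameter vector of the nonparametric model.

    Attributes
    ----------
    v1_std : float
        Central volume of distribution, L per 70 kg body weight.
    ks : float
        Renal elimination rate component, 1/h per 100 mL/min of CLcr.
    ki : float
        Non-renal elimination rate constant, 1/h.
    kcp, kpc : float
        Central->peripheral and peripheral->central transfer rates, 1/h.
    """

    v1_std: float
    ks: float
    ki: float
    kcp: float
    kpc: float

    def __post_init__(self) -> None:
        _require_positive_finite(
            v1_std=self.v1_std, ks=self.ks, ki=self.ki, kcp=self.kcp, kpc=self.kpc
        )

    def as_array(self) -> np.ndarray:
        return np.array([self.v1_std, self.ks, self.ki, self.kcp, self.kpc])


@dataclass(frozen=True)
class Covariates:
    """Patient covariates used by both models.

    ``clcr_ml_min`` is creatinine clearance by Cockcroft-Gault, mL/min.
    """

    weight_kg: float
    clcr_ml_min: float
    sex: str = "F"
    age_years: float | None = None

    def __post_init__(self) -> None:
        if not (math.isfinite(self.weight_kg) and self.weight_kg > 0):
            raise InvalidParameterError(f"weight_kg must be > 0, got {self.weight_kg!r}")
        if not (math.isfinite(self.clcr_ml_min) and self.clcr_ml_min >= 0):
            raise InvalidParameterError(f"clcr_ml_min must be >= 0, got {self.clcr_ml_min!r}")
        if self.sex not in ("F", "M"):
            raise InvalidParameterError(f"sex must be 'F' or 'M', got {self.sex!r}")


@dataclass(frozen=True)
class ResolvedPK:
    """Individual (covariate-resolved) two-compartment parameters."""

    v1_abs: float  # L
    ke: float  # 1/h
    kcp: float  # 1/h
    kpc: float  # 1/h

    def __post_init__(self) -> None:
        _require_positive_finite(v1_abs=self.v1_abs, ke=self.ke, kcp=self.kcp, kpc=self.kpc)

    @property
    def cl(self) -> float:
        """Total body clearance, L/h (Ke * V1 by definition)."""
        return self.ke * self.v1_abs


@dataclass(frozen=True)
class DoseEvent:
    start_time_h: float
    dose_mg: float
    infusion_duration_h: float = 0.5

    def __post_init__(self) -> None:
        _require_positive_finite(
            dose_mg=self.dose_mg, infusion_duration_h=self.infusion_duration_h
        )
        if not math.isfinite(self.start_time_h):
            raise InvalidParameterError("start_time_h must be finite")

    @property
    def rate_mg_h(self) -> float:
        return self.dose_mg / self.infusion_duration_h

    @property
    def end_time_h(self) -> float:
        return self.start_time_h + self.infusion_duration_h


@dataclass(frozen=True)
class DosingRegimen:
    """Ordered dose history plus the repeating interval used for steady state.

    The recorded ``dose_events`` drive concentration prediction and model
    fitting; steady-state exposure assumes the last event's dose repeated
    every ``interval_h`` indefinitely.
    """

    dose_events: tuple[DoseEvent, ...]
    interval_h: float

    def __post_init__(self) -> None:
        if len(self.dose_events) == 0:
            raise InvalidParameterError("at least one dose event is required")
        _require_positive_finite(interval_h=self.interval_h)
        starts = [e.start_time_h for e in self.dose_events]
        if any(b <= a for a, b in zip(starts, starts[1:])):
            raise InvalidParameterError("dose start times must be strictly increasing")
        object.__setattr__(self, "dose_events", tuple(self.dose_events))

    @classmethod
    def multiple_doses(
        cls,
        dose_mg: float,
        n_doses: int,
        interval_h: float = 24.0,
        infusion_duration_h: float = 0.5,
        first_dose_time_h: float = 0.0,
    ) -> "DosingRegimen":
        events = tuple(
            DoseEvent(first_dose_time_h + k * interval_h, dose_mg, infusion_duration_h)
            for k in range(n_doses)
        )
        return cls(events, interval_h)

    @property
    def maintenance_dose(self) -> DoseEvent:
        return self.dose_events[-1]

    @property
    def span_h(self) -> float:
        return self.dose_events[-1].start_time_h + self.interval_h


@dataclass(frozen=True)
class ExposureMetrics:
    """Steady-state exposure summary."""

    auc24_ss: float  # mg.h/L over 24 h
    cmin_ss: float  # mg/L, end of dosing interval
    cmax_ss: float  # mg/L, end of infusion
    t_half_terminal: float  # h
    cl: float  # L/h


# ---------------------------------------------------------------------------
# covariate resolution
# ---------------------------------------------------------------------------


def resolve_parameters(p: PKMicroParams, cov: Covariates) -> ResolvedPK:
    """Apply the covariate model: V1 = v1_std*WT/70, Ke = Ks*CLcr/100 + Ki."""
    v1_abs = p.v1_std * cov.weight_kg / 70.0
    ke = p.ks * cov.clcr_ml_min / 100.0 + p.ki
    try:
        return ResolvedPK(v1_abs=v1_abs, ke=ke, kcp=p.kcp, kpc=p.kpc)
    except InvalidParameterError as exc:
        raise InvalidParameterError(f"covariate resolution produced invalid parameters: {exc}")


def resolve_support(support: np.ndarray, cov: Covariates) -> tuple[np.ndarray, ...]:
    """Vectorized :func:`resolve_parameters` for an (N, 5) support array.

    Returns arrays ``(v1_abs, ke, kcp, kpc)`` each of shape (N,).
    """
    support = np.asarray(support, dtype=float)
    v1 = support[:, 0] * cov.weight_kg / 70.0
    ke = support[:, 1] * cov.clcr_ml_min / 100.0 + support[:, 2]
    return v1, ke, support[:, 3], support[:, 4]


# ---------------------------------------------------------------------------
# closed-form concentration kernel (vectorized over parameter vectors)
# ---------------------------------------------------------------------------


def _eigen(ke: np.ndarray, kcp: np.ndarray, kpc: np.ndarray):
    """Disposition eigenvalues alpha >= beta > 0 and the confluence mask."""
    s = ke + kcp + kpc
    disc = np.sqrt(np.maximum(s * s - 4.0 * ke * kpc, 0.0))
    alpha = 0.5 * (s + disc)
    beta = 0.5 * (s - disc)
    degenerate = disc <= _DEGENERATE_RTOL * s
    return alpha, beta, degenerate


def _unit_rate_conc(alpha, beta, degenerate, kpc, v1, t):
    """Concentration at elapsed time t >= 0 under a unit-rate infusion running
    since time 0 (the integral of the unit-bolus impulse response).

    All parameter arrays must broadcast against ``t``.
    """
    safe = np.where(degenerate, 1.0, (alpha - beta) * v1)
    a1 = (alpha - kpc) / safe
    a2 = (kpc - beta) / safe
    f_reg = a1 * -np.expm1(-alpha * t) / alpha + a2 * -np.expm1(-beta * t) / beta
    # confluent limit alpha == beta == lam: h(t) = e^{-lam t} (1 + (lam-kpc) t)/v1
    lam = 0.5 * (alpha + beta)
    p = (1.0 / lam + (lam - kpc) / lam**2) / v1
    q = (lam - kpc) / (lam * v1)
    f_deg = p - np.exp(-lam * t) * (p + q * t)
    return np.where(degenerate, f_deg, f_reg)


def _conc_grid(
    v1: np.ndarray,
    ke: np.ndarray,
    kcp: np.ndarray,
    kpc: np.ndarray,
    events: Sequence[DoseEvent],
    times: np.ndarray,
) -> np.ndarray:
    """Concentrations for N parameter vectors at T times; returns (N, T)."""
    v1, ke, kcp, kpc = (np.atleast_1d(np.asarray(a, float))[:, None] for a in (v1, ke, kcp, kpc))
    alpha, beta, degenerate = _eigen(ke, kcp, kpc)
    t = np.asarray(times, dtype=float)[None, :]
    out = np.zeros(np.broadcast_shapes(v1.shape, t.shape), dtype=float)
    for ev in events:
        tau = t - ev.start_time_h
        tau_on = np.clip(tau, 0.0, None)
        tau_off = np.clip(tau - ev.infusion_duration_h, 0.0, None)
        contrib = _unit_rate_conc(alpha, beta, degenerate, kpc, v1, tau_on) - _unit_rate_conc(
            alpha, beta, degenerate, kpc, v1, tau_off
        )
        out += ev.rate_mg_h * contrib
    return np.clip(out, 0.0, None)


def predict_concentrations(
    r: ResolvedPK, reg: DosingRegimen, times: Iterable[float]
) -> np.ndarray:
    """Closed-form plasma concentrations (mg/L) at the requested times.

    Times before the first dose return 0.  The profile is continuous across
    infusion-end and dose-start boundaries.
    """
    times = np.asarray(list(times) if not isinstance(times, np.ndarray) else times, dtype=float)
    if np.any(times < 0):
        raise InvalidParameterError("times must be >= 0 (hours since first dose)")
    grid = _conc_grid(
        np.array([r.v1_abs]),
        np.array([r.ke]),
        np.array([r.kcp]),
        np.array([r.kpc]),
        reg.dose_events,
        times,
    )
    return grid[0]


# ---------------------------------------------------------------------------
# steady state (analytic geometric accumulation)
# ---------------------------------------------------------------------------


def _css_grid(
    v1, ke, kcp, kpc, dose_mg: float, interval_h: float, duration_h: float, tau: np.ndarray
) -> np.ndarray:
    """Steady-state concentration at within-interval times tau (0 <= tau <= T).

    Sum of the current dose's response and the geometric tail of all prior
    doses at multiples of the interval.  Requires duration_h <= interval_h.
    Returns (N, len(tau)).
    """
    if duration_h > interval_h:
        raise InvalidParameterError("infusion duration must not exceed the dosing interval")
    v1, ke, kcp, kpc = (np.atleast_1d(np.asarray(a, float))[:, None] for a in (v1, ke, kcp, kpc))
    alpha, beta, degenerate = _eigen(ke, kcp, kpc)
    tau = np.asarray(tau, dtype=float)[None, :]
    rate = dose_mg / duration_h
    T, dur = interval_h, duration_h

    current = _unit_rate_conc(alpha, beta, degenerate, kpc, v1, tau) - _unit_rate_conc(
        alpha, beta, degenerate, kpc, v1, np.clip(tau - dur, 0.0, None)
    )

    # geometric tail: doses at tau + k*T, k >= 1, all fully past their infusion
    safe = np.where(degenerate, 1.0, (alpha - beta) * v1)
    tail = np.zeros(np.broadcast_shapes(v1.shape, tau.shape))
    for lam, coef in ((alpha, (alpha - kpc) / safe), (beta, (kpc - beta) / safe)):
        x = np.exp(-lam * T)
        term = (coef / lam) * (np.exp(-lam * (tau + T - dur)) - np.exp(-lam * (tau + T)))
        tail += np.where(degenerate, 0.0, term / (1.0 - x))

    # confluent limit: per-dose contribution e^{-lam t} (c1 + c2 t)
    lam = 0.5 * (alpha + beta)
    p = (1.0 / lam + (lam - kpc) / lam**2) / v1
    q = (lam - kpc) / (lam * v1)
    e_dur = np.exp(lam * dur)
    c1 = p * (e_dur - 1.0) - q * dur * e_dur
    c2 = q * (e_dur - 1.0)
    x = np.exp(-lam * T)
    sum_exp = np.exp(-lam * tau) * x / (1.0 - x)
    sum_t_exp = np.exp(-lam * tau) * (tau * x / (1.0 - x) + T * x / (1.0 - x) ** 2)
    tail += np.where(degenerate, c1 * sum_exp + c2 * sum_t_exp, 0.0)

    return np.clip(rate * (current + tail), 0.0, None)


def steady_state_metrics_arrays(
    v1, ke, kcp, kpc, dose_mg: float, interval_h: float, duration_h: float
):
    """Vectorized steady-state metrics for N parameter vectors.

    Returns ``(auc24, cmin, cmax, t_half, cl)`` arrays of shape (N,).
    """
    v1a = np.atleast_1d(np.asarray(v1, float))
    kea = np.atleast_1d(np.asarray(ke, float))
    cl = kea * v1a
    auc24 = (24.0 / interval_h) * dose_mg / cl
    css = _css_grid(v1, ke, kcp, kpc, dose_mg, interval_h, duration_h, [duration_h, interval_h])
    cmax = css[:, 0]
    cmin = css[:, 1]
    alpha, beta, degenerate = _eigen(kea, np.atleast_1d(np.asarray(kcp, float)), np.atleast_1d(np.asarray(kpc, float)))
    lam = np.where(degenerate, 0.5 * (alpha + beta), beta)
    t_half = math.log(2.0) / lam
    return auc24, cmin, cmax, t_half, cl


def steady_state_metrics(r: ResolvedPK, reg: DosingRegimen) -> ExposureMetrics:
    """Analytic steady-state exposure assuming the maintenance dose repeated
    every ``reg.interval_h``.

    ``auc24_ss`` follows the linear-PK identity (daily dose)/CL; ``cmax_ss``
    is taken at end of infusion and ``cmin_ss`` at end of the interval.
    """
    ev = reg.maintenance_dose
    auc24, cmin, cmax, t_half, cl = steady_state_metrics_arrays(
        r.v1_abs, r.ke, r.kcp, r.kpc, ev.dose_mg, reg.interval_h, ev.infusion_duration_h
    )
    return ExposureMetrics(
        auc24_ss=float(auc24[0]),
        cmin_ss=float(cmin[0]),
        cmax_ss=float(cmax[0]),
        t_half_terminal=float(t_half[0]),
        cl=float(cl[0]),
    )


def terminal_half_life(r: ResolvedPK) -> float:
    """ln(2)/beta with beta the smaller-magnitude disposition eigenvalue."""
    alpha, beta, degenerate = _eigen(
        np.array([r.ke]), np.array([r.kcp]), np.array([r.kpc])
    )
    lam = 0.5 * (alpha[0] + beta[0]) if degenerate[0] else beta[0]
    return math.log(2.0) / lam


# ---------------------------------------------------------------------------
# reference integrator (test oracle)
# ---------------------------------------------------------------------------


def ode_oracle(r: ResolvedPK, reg: DosingRegimen, times: Iterable[float]) -> np.ndarray:
    """Concentrations by piecewise stiff-safe numerical integration.

    Same contract as :func:`predict_concentrations`; intended as an
    independent cross-check, not for production use.
    """
    times = np.asarray(list(times) if not isinstance(times, np.ndarray) else times, dtype=float)
    if np.any(times < 0):
        raise InvalidParameterError("times must be >= 0")
    t_end = max(times.max(initial=0.0), max(ev.end_time_h for ev in reg.dose_events))
    breaks = {0.0, t_end}
    for ev in reg.dose_events:
        if ev.start_time_h < t_end:
            breaks.add(ev.start_time_h)
        if ev.end_time_h < t_end:
            breaks.add(ev.end_time_h)
    grid = sorted(breaks)

    def rate_at(t0: float, t1: float) -> float:
        mid = 0.5 * (t0 + t1)
        return sum(
            ev.rate_mg_h for ev in reg.dose_events if ev.start_time_h <= mid < ev.end_time_h
        )

    out = np.zeros_like(times)
    state = np.zeros(2)
    for t0, t1 in zip(grid, grid[1:]):
        rate = rate_at(t0, t1)

        def rhs(_t, x, rate=rate):
            return [
                rate - (r.ke + r.kcp) * x[0] + r.kpc * x[1],
                r.kcp * x[0] - r.kpc * x[1],
            ]

        mask = (times > t0) & (times <= t1)
        t_eval = np.sort(np.unique(times[mask]))
        sol = solve_ivp(
            rhs,
            (t0, t1),
            state,
            method="LSODA",
            rtol=1e-11,
            atol=1e-13,
            t_eval=np.unique(np.concatenate([t_eval, [t1]])) if t_eval.size else None,
            dense_output=False,
        )
        if not sol.success:
            raise OracleError(f"integrator failed on segment [{t0}, {t1}]: {sol.message}")
        for tv, x1 in zip(sol.t, sol.y[0]):
            out[mask & np.isclose(times, tv, rtol=0, atol=0)] = x1 / r.v1_abs
        state = sol.y[:, -1]
    out[times <= 0.0] = 0.0
    return np.clip(out, 0.0, None)
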