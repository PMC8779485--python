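"""Population priors and the residual (assay) error model.

Two priors coexist, mirroring the two Bayesian TDM engines:

* a *nonparametric* prior — a discrete set of candidate micro-constant
  vectors (support points) with probability masses, constructed here from
  published summary moments (mean and CV per parameter) because the original
  support table is not public;
* a *parametric* prior — log-normal population distributions on the
  clearance parameterization (CL, V1, Q, V2) with a configurable covariate
  model: creatinine clearance and sex act on CL, body weight scales the
  intercompartmental clearance Q and the peripheral volume V2.

The assay error model is a polynomial standard deviation
``sigma(C) = c0 + c1*C + c2*C^2 + c3*C^3`` with a lower limit of
quantification (LLOQ) of 2 mg/L below which observations are left-censored.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .pk import Covariates, InvalidParameterError, PKMicroParams, ResolvedPK, PARAM_NAMES

__all__ = [
    "ParamMoments",
    "NonparametricPrior",
    "ParametricPrior",
    "AssayErrorModel",
    "build_np_prior",
    "resolve_parametric",
    "macro_from_micro",
    "assay_sd",
]

#: published summary moments of the nonparametric daptomycin model for
#: patients with bone and joint infection: (mean, CV) per micro parameter
DAPTOMYCIN_BJI_MOMENTS = {
    "v1_std": (6.90, 0.394),
    "ks": (0.050, 0.896),
    "ki": (0.060, 0.832),
    "kcp": (0.693, 1.180),
    "kpc": (0.667, 0.977),
}


@dataclass(frozen=True)
class ParamMoments:
    """Mean and coefficient of variation (fraction) per micro parameter."""

    means: dict[str, float]
    cvs: dict[str, float]

    def __post_init__(self) -> None:
        for name in PARAM_NAMES:
            if name not in self.means or name not in self.cvs:
                raise InvalidParameterError(f"missing moments for parameter {name!r}")
            if not (math.isfinite(self.means[name]) and self.means[name] > 0):
                raise InvalidParameterError(f"mean of {name} must be > 0")
            if not (math.isfinite(self.cvs[name]) and self.cvs[name] > 0):
                raise InvalidParameterError(f"CV of {name} must be > 0")

    @classmethod
    def daptomycin_bji(cls) -> "ParamMoments":
        means = {k: v[0] for k, v in DAPTOMYCIN_BJI_MOMENTS.items()}
        cvs = {k: v[1] for k, v in DAPTOMYCIN_BJI_MOMENTS.items()}
        return cls(means=means, cvs=cvs)


@dataclass(frozen=True)
class NonparametricPrior:
    """Discrete prior: N support points (rows of shape (N, 5) in the order
    v1_std, ks, ki, kcp, kpc) with probability masses summing to one."""

    support: np.ndarray
    weights: np.ndarray

    def __post_init__(self) -> None:
        support = np.asarray(self.support, dtype=float)
        weights = np.asarray(self.weights, dtype=float)
        if support.ndim != 2 or support.shape[1] != 5 or support.shape[0] < 1:
            raise InvalidParameterError("support must have shape (N, 5) with N >= 1")
        if weights.shape != (support.shape[0],):
            raise InvalidParameterError("weights must be one per support point")
        if not np.all(np.isfinite(support)) or np.any(support <= 0):
            raise InvalidParameterError("support points must be positive and finite")
        if np.any(weights < 0) or abs(weights.sum() - 1.0) > 1e-12:
            raise InvalidParameterError("weights must be >= 0 and sum to 1 within 1e-12")
        object.__setattr__(self, "support", support)
        object.__setattr__(self, "weights", weights)

    @property
    def n_support(self) -> int:
        return self.support.shape[0]

    def point(self, j: int) -> PKMicroParams:
        return PKMicroParams(*self.support[j])


def build_np_prior(m: ParamMoments, n_support: int, seed: int) -> NonparametricPrior:
    """Draw an equal-weight discrete prior from independent log-normals
    matched to the stated arithmetic mean and CV of each parameter.

    With ``n_support == 1`` the single point sits exactly at the means.
    Reproducible: the same seed yields a bit-identical prior.
    """
    if n_support < 1:
        raise InvalidParameterError("n_support must be >= 1")
    means = np.array([m.means[k] for k in PARAM_NAMES])
    cvs = np.array([m.cvs[k] for k in PARAM_NAMES])
    if n_support == 1:
        support = means[None, :]
    else:
        sigma2 = np.log1p(cvs**2)
        mu = np.log(means) - 0.5 * sigma2
        rng = np.random.default_rng(seed)
        z = rng.standard_normal((n_support, 5))
        support = np.exp(mu + np.sqrt(sigma2) * z)
    weights = np.full(n_support, 1.0 / n_support)
    weights = weights / weights.sum()
    return NonparametricPrior(support=support, weights=weights)


@dataclass(frozen=True)
class ParametricPrior:
    """Log-normal population prior on the clearance parameterization.

    Typical values are for the reference patient (70 kg, CLcr 100 mL/min,
    female); ``omega_*`` are between-subject SDs on the log scale.  The
    covariate model is declared explicitly:

    * CL: ``clcr_form == "linear"`` multiplies by
      ``1 + theta_clcr*(CLcr/100 - 1)`` (theta_clcr is the renal fraction of
      clearance); ``"power"`` multiplies by ``(CLcr/100)**theta_clcr``.
      Males get the extra factor ``theta_sex_male``.
    * Q and V2: multiplied by ``(WT/70)**weight_power`` (default linear).

    Body temperature is deliberately absent from the covariate model.
    """

    tv_cl: float  # L/h
    tv_v1: float  # L
    tv_q: float  # L/h
    tv_v2: float  # L
    omega_cl: float = 0.35
    omega_v1: float = 0.35
    omega_q: float = 0.7
    omega_v2: float = 0.7
    clcr_form: str = "linear"
    theta_clcr: float = 0.4545
    theta_sex_male: float = 1.0
    weight_power_q: float = 1.0
    weight_power_v2: float = 1.0

    def __post_init__(self) -> None:
        for name in ("tv_cl", "tv_v1", "tv_q", "tv_v2"):
            v = getattr(self, name)
            if not (math.isfinite(v) and v > 0):
                raise InvalidParameterError(f"{name} must be positive and finite")
        for name in ("omega_cl", "omega_v1", "omega_q", "omega_v2"):
            v = getattr(self, name)
            if not (math.isfinite(v) and v >= 0):
                raise InvalidParameterError(f"{name} must be >= 0")
        if self.clcr_form not in ("linear", "power"):
            raise InvalidParameterError("clcr_form must be 'linear' or 'power'")
        if self.theta_sex_male <= 0:
            raise InvalidParameterError("theta_sex_male must be > 0")

    @property
    def omegas(self) -> np.ndarray:
        return np.array([self.omega_cl, self.omega_v1, self.omega_q, self.omega_v2])

    def covariate_typicals(self, cov: Covariates) -> np.ndarray:
        """Covariate-adjusted typical values (CL, V1, Q, V2)."""
        rel_clcr = cov.clcr_ml_min / 100.0
        if self.clcr_form == "linear":
            f_clcr = 1.0 + self.theta_clcr * (rel_clcr - 1.0)
        else:
            f_clcr = rel_clcr**self.theta_clcr if rel_clcr > 0 else 0.0
        if f_clcr <= 0 or not math.isfinite(f_clcr):
            raise InvalidParameterError(
                f"CLcr covariate multiplier is non-positive ({f_clcr}) at CLcr="
                f"{cov.clcr_ml_min} mL/min"
            )
        cl = self.tv_cl * f_clcr * (self.theta_sex_male if cov.sex == "M" else 1.0)
        rel_wt = cov.weight_kg / 70.0
        q = self.tv_q * rel_wt**self.weight_power_q
        v2 = self.tv_v2 * rel_wt**self.weight_power_v2
        return np.array([cl, self.tv_v1, q, v2])

    @classmethod
    def from_micro_moments(cls, m: ParamMoments, **overrides) -> "ParametricPrior":
        """Typical values implied by micro-constant moments at the reference
        patient: CL = (Ks+Ki)*V1, Q = Kcp*V1, V2 = Q/Kpc; the CLcr slope is
        the renal clearance fraction Ks/(Ks+Ki)."""
        v1 = m.means["v1_std"]
        ke = m.means["ks"] + m.means["ki"]
        q = m.means["kcp"] * v1
        defaults = dict(
            tv_cl=ke * v1,
            tv_v1=v1,
            tv_q=q,
            tv_v2=q / m.means["kpc"],
            theta_clcr=m.means["ks"] / ke,
        )
        defaults.update(overrides)
        return cls(**defaults)


def resolve_parametric(p: ParametricPrior, cov: Covariates) -> ResolvedPK:
    """Covariate-adjusted typical values converted to micro-constants."""
    cl, v1, q, v2 = p.covariate_typicals(cov)
    return macro_to_micro(cl, v1, q, v2)


def macro_to_micro(cl: float, v1: float, q: float, v2: float) -> ResolvedPK:
    """(CL, V1, Q, V2) -> micro constants: ke = CL/V1, kcp = Q/V1, kpc = Q/V2."""
    return ResolvedPK(v1_abs=v1, ke=cl / v1, kcp=q / v1, kpc=q / v2)


def macro_from_micro(r: ResolvedPK) -> tuple[float, float, float, float]:
    """Inverse of :func:`macro_to_micro`; exact algebraic round-trip."""
    cl = r.ke * r.v1_abs
    q = r.kcp * r.v1_abs
    v2 = q / r.kpc
    return cl, r.v1_abs, q, v2


@dataclass(frozen=True)
class AssayErrorModel:
    """Polynomial assay SD, sigma(C) = c0 + c1 C + c2 C^2 + c3 C^3 (mg/L).

    Defaults: c0 = 0.5 mg/L (a quarter of the LLOQ) and c1 = 0.1 (~the
    assay's stated interday precision); LLOQ = 2 mg/L.
    """

    c0: float = 0.5
    c1: float = 0.1
    c2: float = 0.0
    c3: float = 0.0
    lloq: float = 2.0

    def __post_init__(self) -> None:
        if not (math.isfinite(self.lloq) and self.lloq > 0):
            raise InvalidParameterError("lloq must be > 0")
        if self.c0 <= 0 and self.c1 <= 0 and self.c2 <= 0 and self.c3 <= 0:
            raise InvalidParameterError("assay sigma must be positive somewhere")
        # quick positivity screen over the working range
        grid = np.linspace(0.0, 200.0, 401)
        if np.any(self.sd(grid) <= 0):
            raise InvalidParameterError("assay sigma must be > 0 for all C in [0, 200] mg/L")

    def sd(self, conc) -> np.ndarray | float:
        c = np.asarray(conc, dtype=float)
        out = self.c0 + self.c1 * c + self.c2 * c**2 + self.c3 * c**3
        return float(out) if np.isscalar(conc) else out


def assay_sd(e: AssayErrorModel, conc: float) -> float:
    """sigma at a concentration (mg/L); raises if configuration yields sigma <= 0."""
    if conc < 0:
        raise InvalidParameterError("conc must be >= 0")
    s = float(e.sd(conc))
    if not (math.isfinite(s) and s > 0):
        raise InvalidParameterError(f"assay sigma is non-positive ({s}) at C={conc}")
    return s
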