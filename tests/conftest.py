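import numpy as np
import pytest

from dapdose import (
    AssayErrorModel,
    Covariates,
    DosingRegimen,
    ParamMoments,
    PKMicroParams,
    ResolvedPK,
)
from dapdose.bayes import PosteriorWeights


@pytest.fixture
def table_moments() -> ParamMoments:
    return ParamMoments.daptomycin_bji()


@pytest.fixture
def mean_params() -> PKMicroParams:
    return PKMicroParams(6.90, 0.050, 0.060, 0.693, 0.667)


@pytest.fixture
def ref_cov() -> Covariates:
    return Covariates(weight_kg=70.0, clcr_ml_min=100.0, sex="F")


@pytest.fixture
def q24_regimen() -> DosingRegimen:
    return DosingRegimen.multiple_doses(500.0, n_doses=6, interval_h=24.0, infusion_duration_h=0.5)


@pytest.fixture
def error_model() -> AssayErrorModel:
    return AssayErrorModel()


def random_resolved(rng: np.random.Generator) -> ResolvedPK:
    """A random but physiologic two-compartment parameter set."""
    return ResolvedPK(
        v1_abs=rng.uniform(3.0, 15.0),
        ke=rng.uniform(0.02, 0.3),
        kcp=rng.uniform(0.05, 2.0),
        kpc=rng.uniform(0.05, 2.0),
    )


def random_regimen(rng: np.random.Generator) -> DosingRegimen:
    return DosingRegimen.multiple_doses(
        dose_mg=rng.uniform(200.0, 900.0),
        n_doses=int(rng.integers(1, 6)),
        interval_h=24.0,
        infusion_duration_h=rng.uniform(0.25, 2.0),
    )


def discrete_cl_fit(
    cl_values, weights, regimen: DosingRegimen, v1: float = 10.0
) -> PosteriorWeights:
    """A discrete posterior whose support points have exactly the requested
    clearances (CLcr = 0 so that ke = ki, weight 70 kg so V1 = v1_std)."""
    cl_values = np.asarray(cl_values, dtype=float)
    support = np.column_stack(
        [
            np.full_like(cl_values, v1),
            np.full_like(cl_values, 0.05),  # inert: CLcr = 0
            cl_values / v1,
            np.full_like(cl_values, 0.5),
            np.full_like(cl_values, 0.5),
        ]
    )
    cov = Covariates(weight_kg=70.0, clcr_ml_min=0.0, sex="F")
    return PosteriorWeights(support, np.asarray(weights, float), cov, regimen)
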