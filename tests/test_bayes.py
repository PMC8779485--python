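"""Individual Bayesian estimation: censored Gaussian likelihood, discrete
posterior reweighting, MAP optimization, posterior prediction/exposure."""

import math

import numpy as np
import pytest
from scipy.stats import norm

from dapdose import (
    AssayErrorModel,
    Covariates,
    DosingRegimen,
    ParametricPrior,
    ResolvedPK,
    build_np_prior,
    log_likelihood,
    map_fit,
    np_posterior,
    posterior_exposure,
    posterior_predict,
    predict_concentrations,
    resolve_parameters,
)
from dapdose.bayes import DegeneratePosteriorError, ObservationSet, PosteriorWeights

from conftest import discrete_cl_fit

_LOG_SQRT_2PI = 0.5 * math.log(2 * math.pi)


def _obs_from(r, reg, cov, times, conc=None, blq=None):
    times = np.asarray(times, float)
    if conc is None:
        conc = predict_concentrations(r, reg, times)
    blq = np.zeros(times.size, bool) if blq is None else np.asarray(blq, bool)
    return ObservationSet(times, np.asarray(conc, float), blq, cov, reg)


@pytest.fixture
def patient(ref_cov, q24_regimen):
    r = ResolvedPK(8.0, 0.12, 0.6, 0.5)
    return r, q24_regimen, ref_cov


class TestLogLikelihood:
    def test_zero_residuals_attain_maximum(self, patient, error_model):
        r, reg, cov = patient
        obs = _obs_from(r, reg, cov, [119.9, 120.5, 125.5])
        sd = error_model.sd(obs.conc_mg_l)
        expected = -np.sum(np.log(sd) + _LOG_SQRT_2PI)
        assert log_likelihood(r, obs, error_model) == pytest.approx(expected, rel=1e-12)

    def test_one_sigma_residual_costs_half_plus_log_norm(self, patient, error_model):
        r, reg, cov = patient
        base = _obs_from(r, reg, cov, [119.9, 120.5])
        t_new = 125.5
        pred = predict_concentrations(r, reg, [t_new])[0]
        sd = error_model.sd(pred)
        extra = _obs_from(
            r, reg, cov, [119.9, 120.5, t_new],
            conc=np.append(base.conc_mg_l, pred + sd),
        )
        drop = log_likelihood(r, base, error_model) - log_likelihood(r, extra, error_model)
        assert drop == pytest.approx(0.5 + math.log(sd * math.sqrt(2 * math.pi)), rel=1e-12)

    def test_matches_brute_force_density(self, error_model):
        rng = np.random.default_rng(8)
        from conftest import random_regimen, random_resolved

        for _ in range(20):
            r, reg = random_resolved(rng), random_regimen(rng)
            cov = Covariates(rng.uniform(40, 120), rng.uniform(20, 180), "F")
            t = np.sort(rng.uniform(0.5, reg.span_h, 4))
            conc = np.clip(
                predict_concentrations(r, reg, t) + rng.normal(0, 2, 4), 0.0, None
            )
            blq = conc < error_model.lloq
            obs = ObservationSet(t, conc, blq, cov, reg)
            # independent evaluation: plain loop over scipy densities
            pred = predict_concentrations(r, reg, t)
            ref = 0.0
            for p, c, b in zip(pred, conc, blq):
                s = error_model.sd(p)
                if b:
                    ref += norm.logcdf(error_model.lloq, loc=p, scale=s)
                else:
                    ref += norm.logpdf(c, loc=p, scale=s)
            assert log_likelihood(r, obs, error_model) == pytest.approx(ref, abs=1e-12)


class TestNpPosterior:
    def test_no_data_returns_prior_exactly(self, table_moments, ref_cov, q24_regimen, error_model):
        prior = build_np_prior(table_moments, 300, seed=2)
        obs = ObservationSet.empty(ref_cov, q24_regimen)
        post = np_posterior(prior, obs, error_model)
        assert np.array_equal(post.weights, prior.weights)

    def test_indistinguishable_points_keep_prior_ratio(self, ref_cov, q24_regimen, error_model):
        row = np.array([6.9, 0.05, 0.06, 0.7, 0.7])
        prior_support = np.vstack([row, row])
        from dapdose.priors import NonparametricPrior

        prior = NonparametricPrior(prior_support, np.array([0.3, 0.7]))
        r = resolve_parameters(prior.point(0), ref_cov)
        obs = _obs_from(r, q24_regimen, ref_cov, [119.9, 120.5, 125.5])
        post = np_posterior(prior, obs, error_model)
        assert post.weights == pytest.approx([0.3, 0.7], abs=1e-12)

    def test_concentrates_on_generating_point(self, table_moments, q24_regimen):
        prior = build_np_prior(table_moments, 500, seed=3)
        cov = Covariates(80.0, 90.0, "M")
        j = 123
        r = resolve_parameters(prior.point(j), cov)
        obs = _obs_from(r, q24_regimen, cov, [119.9, 120.5, 125.5])
        tight = AssayErrorModel(c0=0.01, c1=1e-6)
        post = np_posterior(prior, obs, tight)
        assert post.weights[j] > 0.99

    def test_order_of_observations_is_irrelevant(self, table_moments, q24_regimen, error_model):
        prior = build_np_prior(table_moments, 200, seed=5)
        cov = Covariates(75.0, 110.0, "F")
        t = np.array([119.9, 120.5, 125.5])
        c = np.array([18.0, 70.0, 40.0])
        fwd = np_posterior(prior, ObservationSet(t, c, np.zeros(3, bool), cov, q24_regimen), error_model)
        rev = np_posterior(
            prior, ObservationSet(t[::-1].copy(), c[::-1].copy(), np.zeros(3, bool), cov, q24_regimen), error_model
        )
        assert fwd.weights == pytest.approx(rev.weights, abs=1e-14)

    def test_exact_fit_observation_never_decreases_weight(self, table_moments, q24_regimen, error_model):
        prior = build_np_prior(table_moments, 200, seed=6)
        cov = Covariates(70.0, 100.0, "F")
        j = 50
        r = resolve_parameters(prior.point(j), cov)
        t3 = [119.9, 120.5, 125.5]
        obs3 = _obs_from(r, q24_regimen, cov, t3)
        obs4 = _obs_from(r, q24_regimen, cov, t3 + [130.0])
        w3 = np_posterior(prior, obs3, error_model).weights[j]
        w4 = np_posterior(prior, obs4, error_model).weights[j]
        assert w4 >= w3 - 1e-15

    def test_degenerate_posterior_raises(self, table_moments, q24_regimen, error_model):
        prior = build_np_prior(table_moments, 50, seed=7)
        cov = Covariates(70.0, 100.0, "F")
        huge = np.array([1e300, 1e300, 1e300])
        obs = ObservationSet(np.array([119.9, 120.5, 125.5]), huge, np.zeros(3, bool), cov, q24_regimen)
        with pytest.raises(DegeneratePosteriorError):
            np_posterior(prior, obs, error_model)

    def test_weights_always_sum_to_one(self, table_moments, q24_regimen, error_model):
        prior = build_np_prior(table_moments, 400, seed=8)
        cov = Covariates(90.0, 60.0, "M")
        obs = ObservationSet(
            np.array([119.9, 120.5, 125.5]),
            np.array([25.0, 90.0, 55.0]),
            np.zeros(3, bool),
            cov,
            q24_regimen,
        )
        post = np_posterior(prior, obs, error_model)
        assert post.weights.sum() == pytest.approx(1.0, abs=1e-12)


class TestMapFit:
    def test_zero_observations_returns_prior_mode_exactly(self, table_moments, ref_cov, q24_regimen, error_model):
        p = ParametricPrior.from_micro_moments(table_moments)
        fit = map_fit(p, ObservationSet.empty(ref_cov, q24_regimen), error_model)
        assert np.array_equal(fit.theta, p.covariate_typicals(ref_cov))

    def test_rich_noiseless_data_recovers_cl_and_v1(self, table_moments, q24_regimen):
        true = ResolvedPK(8.0, 0.12, 0.6, 0.5)
        cov = Covariates(80.0, 95.0, "M")
        t = 120.0 + np.array([0.25, 0.5, 1.0, 2.0, 4.0, 8.0, 16.0, 23.9])
        obs = _obs_from(true, q24_regimen, cov, t)
        wide = ParametricPrior.from_micro_moments(
            table_moments, omega_cl=1.0, omega_v1=1.0, omega_q=1.0, omega_v2=1.0
        )
        fit = map_fit(wide, obs, AssayErrorModel(c0=0.05, c1=0.001))
        assert fit.theta[0] == pytest.approx(true.cl, rel=0.01)
        assert fit.theta[1] == pytest.approx(true.v1_abs, rel=0.01)

    def test_solution_no_worse_than_prior_mode(self, table_moments, q24_regimen, error_model):
        p = ParametricPrior.from_micro_moments(table_moments)
        cov = Covariates(72.0, 80.0, "F")
        obs = ObservationSet(
            np.array([119.9, 120.5, 125.5]),
            np.array([20.0, 75.0, 45.0]),
            np.zeros(3, bool),
            cov,
            q24_regimen,
        )
        fit = map_fit(p, obs, error_model)
        mode = map_fit(p, ObservationSet.empty(cov, q24_regimen), error_model)
        obj_at_mode = -log_likelihood(mode.resolved, obs, error_model)
        assert fit.objective <= obj_at_mode + 1e-9

    def test_np_and_map_agree_in_identifiable_limit(self, table_moments, q24_regimen):
        """With rich low-noise data both engines must localize clearance."""
        prior = build_np_prior(table_moments, 2000, seed=21)
        cov = Covariates(70.0, 100.0, "F")
        j = 700
        true = resolve_parameters(prior.point(j), cov)
        t = 120.0 + np.array([0.25, 0.5, 1.0, 2.0, 4.0, 8.0, 16.0, 23.9])
        tight = AssayErrorModel(c0=0.05, c1=0.005)
        obs = _obs_from(true, q24_regimen, cov, t)
        post = np_posterior(prior, obs, tight)
        v1, ke, _, _ = post.resolved_arrays()
        np_cl = float(post.weights @ (ke * v1))
        wide = ParametricPrior.from_micro_moments(
            table_moments, omega_cl=1.0, omega_v1=1.0, omega_q=1.0, omega_v2=1.0
        )
        map_cl = map_fit(wide, obs, tight).theta[0]
        assert abs(np_cl - map_cl) / map_cl < 0.05


class TestPosteriorPredictAndExposure:
    def test_one_point_posterior_equals_direct_prediction(self, q24_regimen):
        fit = discrete_cl_fit([0.8], [1.0], q24_regimen)
        r = ResolvedPK(10.0, 0.08, 0.5, 0.5)
        t = np.linspace(0.5, 130.0, 9)
        assert posterior_predict(fit, t) == pytest.approx(
            predict_concentrations(r, q24_regimen, t), rel=1e-12
        )

    def test_predictions_are_convex_combinations(self, table_moments, q24_regimen, error_model):
        prior = build_np_prior(table_moments, 100, seed=9)
        cov = Covariates(85.0, 70.0, "M")
        obs = ObservationSet(
            np.array([119.9, 120.5, 125.5]),
            np.array([22.0, 80.0, 50.0]),
            np.zeros(3, bool),
            cov,
            q24_regimen,
        )
        post = np_posterior(prior, obs, error_model)
        t = np.linspace(1.0, 140.0, 13)
        from dapdose.pk import _conc_grid

        v1, ke, kcp, kpc = post.resolved_arrays()
        grid = _conc_grid(v1, ke, kcp, kpc, q24_regimen.dose_events, t)
        pred = posterior_predict(post, t)
        assert np.all(pred >= grid.min(axis=0) - 1e-12)
        assert np.all(pred <= grid.max(axis=0) + 1e-12)
        # brute-force weighted sum
        ref = np.array([(post.weights * grid[:, k]).sum() for k in range(t.size)])
        assert pred == pytest.approx(ref, abs=1e-12)

    def test_exposure_one_point_unit_clearance(self, q24_regimen):
        reg = DosingRegimen.multiple_doses(666.0, 1, 24.0, 0.5)
        fit = discrete_cl_fit([1.0], [1.0], reg)
        assert posterior_exposure(fit).metrics.auc24_ss == pytest.approx(666.0, rel=1e-12)

    def test_exposure_two_point_hand_example(self):
        reg = DosingRegimen.multiple_doses(100.0, 1, 24.0, 0.5)
        fit = discrete_cl_fit([0.5, 1.0], [0.5, 0.5], reg)
        assert posterior_exposure(fit).metrics.auc24_ss == pytest.approx(150.0, rel=1e-12)

    def test_expected_auc_is_dose_times_expected_inverse_clearance(self, table_moments, q24_regimen):
        prior = build_np_prior(table_moments, 250, seed=10)
        cov = Covariates(66.0, 120.0, "F")
        fit = PosteriorWeights(prior.support, prior.weights, cov, q24_regimen)
        exp = posterior_exposure(fit)
        v1, ke, _, _ = fit.resolved_arrays()
        daily = q24_regimen.maintenance_dose.dose_mg  # q24h
        ref = daily * float(fit.weights @ (1.0 / (ke * v1)))
        assert exp.metrics.auc24_ss == pytest.approx(ref, rel=1e-10)
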