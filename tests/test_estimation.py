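"""Mixed-effects machinery: Laplace likelihood, fitting, bootstrap, VPC."""

import numpy as np
import pytest
from scipy.integrate import quad

from ferrodyn.cohort import CohortSpec, simulate_cohort, subjects_from_table
from ferrodyn.estimation import (PopulationModel, SubjectRecord, bootstrap,
                                 fit_population, individual_prediction,
                                 marginal_loglik, subject_exposure,
                                 visual_predictive_check)
from ferrodyn.exceptions import DomainError


@pytest.fixture(scope="module")
def two_obs_subject():
    return SubjectRecord(id=1, weight=45.0, dose_per_kg=40.0, cmpl=0.2,
                         obs_times=np.array([0.0, 2000.0]),
                         obs=np.array([4000.0, 3500.0]))


def _quadrature_neg2ll(rec, pop):
    """Independent 1-D oracle: adaptive quadrature of the marginal density
    over eta, with the occasion effect pinned at zero (omega_iov ~ 0)."""
    y = rec.obs[1:]

    def integrand(eta):
        F = individual_prediction(rec, pop, eta=eta, kappa=np.zeros(1))[1:]
        w = pop.sigma * F
        loglik = -0.5 * np.sum(np.log(2 * np.pi * w ** 2) + ((y - F) / w) ** 2)
        logprior = -0.5 * (np.log(2 * np.pi * pop.omega_iiv)
                           + eta ** 2 / pop.omega_iiv)
        return np.exp(loglik + logprior)

    half_width = 8 * np.sqrt(pop.omega_iiv)
    val, _ = quad(integrand, -half_width, half_width, limit=200)
    return -2.0 * np.log(val)


class TestMarginalLoglik:
    def test_matches_quadrature_oracle_small_variance(self, two_obs_subject):
        pop = PopulationModel(omega_iiv=1e-4, omega_iov=1e-12)
        lap = marginal_loglik([two_obs_subject], pop)
        assert lap == pytest.approx(_quadrature_neg2ll(two_obs_subject, pop),
                                    abs=1e-4)

    def test_close_to_quadrature_at_fitted_variance(self, two_obs_subject):
        pop = PopulationModel(omega_iiv=0.082, omega_iov=1e-12)
        lap = marginal_loglik([two_obs_subject], pop)
        assert lap == pytest.approx(_quadrature_neg2ll(two_obs_subject, pop),
                                    abs=0.05)

    def test_collapses_to_weighted_least_squares(self, two_obs_subject):
        """As both variances shrink the marginal objective tends to the
        fixed-effect proportional-error WLS objective at zero random
        effects."""
        pop = PopulationModel(omega_iiv=1e-12, omega_iov=1e-12)
        lap = marginal_loglik([two_obs_subject], pop)
        y = two_obs_subject.obs[1:]
        F = individual_prediction(two_obs_subject, pop, eta=0.0,
                                  kappa=np.zeros(1))[1:]
        w = pop.sigma * F
        wls = np.sum(np.log(2 * np.pi * w ** 2) + ((y - F) / w) ** 2)
        assert lap == pytest.approx(wls, abs=1e-6)

    def test_objective_invariant_to_subject_order(self, small_cohort):
        _, _, records = small_cohort
        pop = PopulationModel()
        assert marginal_loglik(records, pop) == pytest.approx(
            marginal_loglik(records[::-1], pop), rel=1e-12)

    def test_objective_worsens_away_from_truth(self, small_cohort, truth):
        _, _, records = small_cohort
        at_truth = marginal_loglik(records, truth)
        far = PopulationModel(sigma=truth.sigma * 8.0)
        assert marginal_loglik(records, far) > at_truth

    def test_rejects_zero_sigma(self, two_obs_subject):
        with pytest.raises(DomainError):
            marginal_loglik([two_obs_subject], PopulationModel(sigma=0.0))


class TestIndividualPrediction:
    def test_zero_random_effects_give_population_prediction(self,
                                                            two_obs_subject):
        pop = PopulationModel()
        pred = individual_prediction(two_obs_subject, pop)
        assert pred[0] == two_obs_subject.baseline
        assert pred.shape == two_obs_subject.obs.shape

    def test_eta_scales_slope_lognormally(self, two_obs_subject):
        """eta = ln 2 must reproduce a doubled typical slope exactly."""
        pop = PopulationModel(slope=2.0)
        doubled = PopulationModel(slope=4.0)
        a = individual_prediction(two_obs_subject, pop, eta=np.log(2.0))
        b = individual_prediction(two_obs_subject, doubled, eta=0.0)
        assert np.allclose(a, b, rtol=1e-12)

    def test_continuity_in_eta(self, two_obs_subject):
        pop = PopulationModel()
        rng = np.random.default_rng(6)
        for eta in rng.normal(0.0, 0.3, size=5):
            f = individual_prediction(two_obs_subject, pop, eta=eta)[-1]
            f_eps = individual_prediction(two_obs_subject, pop,
                                          eta=eta + 1e-6)[-1]
            assert abs(f_eps - f) < 1e-3

    def test_exposure_uses_compliance_correction(self, two_obs_subject):
        pop = PopulationModel()
        full = SubjectRecord(id=2, weight=45.0, dose_per_kg=40.0, cmpl=0.0,
                             obs_times=two_obs_subject.obs_times,
                             obs=two_obs_subject.obs)
        assert subject_exposure(two_obs_subject, pop) == pytest.approx(
            0.8 * subject_exposure(full, pop))


class TestFitPopulation:
    def test_noiseless_cohort_recovers_slope(self):
        """Zero noise, zero random effects: the generating slope must be
        recovered to 3 significant digits from a slope-only fit."""
        gen = PopulationModel(slope=4.81, omega_iiv=0.0, omega_iov=0.0,
                              sigma=0.0)
        spec = CohortSpec(n_subjects=6, max_followup_years=5.0,
                          p_complete=1.0)
        table, _ = simulate_cohort(spec, gen, seed=21)
        records = subjects_from_table(table)
        # a tiny fixed sigma makes the least-squares term dominate the
        # Laplace determinant term, so the optimum sits at the truth
        init = PopulationModel(slope=2.0, omega_iiv=1e-10, omega_iov=1e-10,
                               sigma=0.01)
        fit = fit_population(records, init=init, estimate=("slope",),
                             n_starts=2, compute_se=False)
        assert fit.converged
        assert fit.estimates["slope"] == pytest.approx(4.81, rel=5e-3)

    def test_full_fit_on_small_cohort(self, small_cohort):
        _, _, records = small_cohort
        fit = fit_population(records, n_starts=1)
        assert fit.converged
        assert np.isfinite(fit.ofv)
        # a small cohort constrains the parameters only loosely
        assert 1.0 < fit.estimates["slope"] < 25.0
        assert 0.05 < fit.estimates["sigma"] < 0.6
        assert len(fit.eb_estimates) == len(records)

    def test_unknown_parameter_rejected(self, small_cohort):
        _, _, records = small_cohort
        with pytest.raises(DomainError):
            fit_population(records, estimate=("kout",))


class TestBootstrap:
    def test_identity_resample_reproduces_fit(self, small_cohort):
        _, _, records = small_cohort
        direct = fit_population(records, n_starts=1, compute_se=False)
        boot = bootstrap(records, n_samples=1, seed=0,
                         sampler=lambda rng, n: np.arange(n))
        assert boot["n_failed"] == 0
        row = boot["replicates"].iloc[0]
        for name, value in direct.estimates.items():
            assert row[name] == pytest.approx(value, rel=1e-6)

    def test_resampling_summary(self, small_cohort):
        _, _, records = small_cohort
        boot = bootstrap(records, n_samples=3, seed=1)
        done = 3 - boot["n_failed"]
        assert len(boot["replicates"]) == done
        if done > 1:
            assert set(boot["summary"].columns) == {"mean", "cv_percent"}

    def test_invalid_sample_count(self, small_cohort):
        _, _, records = small_cohort
        with pytest.raises(DomainError):
            bootstrap(records, n_samples=0)


class TestVisualPredictiveCheck:
    def test_reproducible_under_seed(self, small_cohort, truth):
        _, _, records = small_cohort
        a = visual_predictive_check(records, truth, n_sim=100, seed=3)
        b = visual_predictive_check(records, truth, n_sim=100, seed=3)
        assert a.equals(b)

    def test_bands_widen_with_inflated_variability(self, small_cohort, truth):
        _, _, records = small_cohort
        narrow = visual_predictive_check(records, truth, n_sim=100, seed=4)
        inflated = PopulationModel(omega_iiv=4 * truth.omega_iiv,
                                   omega_iov=4 * truth.omega_iov,
                                   sigma=2 * truth.sigma)
        wide = visual_predictive_check(records, inflated, n_sim=100, seed=4)
        width_narrow = (narrow["sim_hi"] - narrow["sim_lo"]).mean()
        width_wide = (wide["sim_hi"] - wide["sim_lo"]).mean()
        assert width_wide > width_narrow

    def test_minimum_replicates_enforced(self, small_cohort, truth):
        _, _, records = small_cohort
        with pytest.raises(DomainError):
            visual_predictive_check(records, truth, n_sim=10)
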