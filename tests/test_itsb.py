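"""ITSB estimation: objective arithmetic, MAP behaviour, population update,
convergence and diagnostics."""

import numpy as np
import pandas as pd
import pytest

from hcpk.cohort import Observation, StudyDesign, SubjectRecord, generate
from hcpk.config import RunConfig
from hcpk.itsb import (FitSettings, fit, map_estimate, neg_log_posterior,
                       shrinkage, update_population, weighted_residuals)
from hcpk.itsb import _Workspace
from hcpk.pkmodel import DoseEvent, PKParameters, simulate_free
from hcpk.population import PopulationModel, to_transformed
from hcpk.binding import BindingSystem, total_from_free


CFG = RunConfig()
POP = CFG.generating_population()
SETTINGS = CFG.fit_settings()


def make_subject(theta, design=None, seed=0, n_obs_noise=0.0,
                 pop=POP) -> SubjectRecord:
    """One subject with noise-free (or lightly noised) observations
    simulated from a known theta under the standard sparse design."""
    design = design or StudyDesign(n_subjects=1)
    rng = np.random.default_rng(seed)
    V, CL, RC = theta
    params = PKParameters(V=V, CL=CL, ka=SETTINGS.ka, F_bio=SETTINGS.F_bio)
    doses = tuple(DoseEvent(time=24.0 * day + t, amount=a)
                  for day in range(4)
                  for t, a in zip((7.0, 13.0, 19.0), (10.0, 5.0, 2.5)))
    system = BindingSystem(600_000.0, 700.0, RC)
    times = np.array([3 * 24 + 8.0, 3 * 24 + 13.5])
    free = simulate_free(doses, params, times)
    total = np.atleast_1d(total_from_free(free, system))
    obs = []
    for t, f, tt in zip(times, free, total):
        obs.append(Observation(t, f * (1 + n_obs_noise * rng.standard_normal()),
                               "free", "low"))
        obs.append(Observation(t, tt * (1 + n_obs_noise * rng.standard_normal()),
                               "total", "low"))
    return SubjectRecord(id="T1", weight=70.0, TotA=600_000.0,
                         TotC_total=700.0, doses=doses,
                         observations=tuple(obs))


class TestNegLogPosterior:
    def test_exact_fit_at_mu_leaves_only_normalisation(self):
        subj = make_subject(POP.mu)
        got = neg_log_posterior(POP.mu, subj, POP, SETTINGS)
        ws = _Workspace(subj, SETTINGS)
        f = ws.predict(POP.mu_transformed)
        v = POP.sigma_add**2 + (POP.sigma_prop * f) ** 2
        assert got == pytest.approx(0.5 * np.sum(np.log(v)), rel=1e-12)

    def test_hand_computed_two_observation_case(self):
        """Scalar arithmetic oracle on a 2-observation likelihood + prior."""
        subj = make_subject(POP.mu)
        theta = (450.0, 250.0, 0.2)
        ws = _Workspace(subj, SETTINGS)
        f = ws.predict(to_transformed(*theta))
        y = ws.values
        v = POP.sigma_add**2 + (POP.sigma_prop * f) ** 2
        like = 0.5 * np.sum((y - f) ** 2 / v + np.log(v))
        dev = to_transformed(*theta) - POP.mu_transformed
        prior = 0.5 * np.sum(dev**2 / np.asarray(POP.omega) ** 2)
        assert neg_log_posterior(theta, subj, POP, SETTINGS) == pytest.approx(
            like + prior, rel=1e-12)

    def test_degenerate_prior_is_infinite_off_mu(self):
        subj = make_subject(POP.mu)
        pop0 = POP.with_updates(omega=(0.0, 0.0, 0.0))
        assert neg_log_posterior(POP.mu, subj, pop0, SETTINGS) < np.inf
        off = (POP.mu[0] * 1.1, POP.mu[1], POP.mu[2])
        assert neg_log_posterior(off, subj, pop0, SETTINGS) == np.inf


class TestMapEstimate:
    def test_rich_noise_free_data_recovers_truth(self):
        """24 draws/day, both analytes, no noise -> recovery within 1%."""
        truth = (350.0, 190.0, 0.25)
        design = StudyDesign(n_subjects=1)
        rng = np.random.default_rng(0)
        V, CL, RC = truth
        params = PKParameters(V=V, CL=CL, ka=SETTINGS.ka, F_bio=SETTINGS.F_bio)
        doses = tuple(DoseEvent(time=24.0 * day + t, amount=a)
                      for day in range(4)
                      for t, a in zip((7.0, 13.0, 19.0), (10.0, 5.0, 2.5)))
        system = BindingSystem(600_000.0, 700.0, RC)
        times = 3 * 24 + np.linspace(7.25, 30.0, 24)
        free = simulate_free(doses, params, times)
        total = np.atleast_1d(total_from_free(free, system))
        obs = tuple(Observation(t, v, "free", "low")
                    for t, v in zip(times, free)) + \
              tuple(Observation(t, v, "total", "low")
                    for t, v in zip(times, total))
        subj = SubjectRecord(id="R", weight=70.0, TotA=600_000.0,
                             TotC_total=700.0, doses=doses, observations=obs)
        # residual model consistent with the noise-free data, so the
        # likelihood dominates the prior
        pop = POP.with_updates(sigma_add=0.1, sigma_prop=0.01)
        est = map_estimate(subj, pop, settings=SETTINGS)
        assert est[0] == pytest.approx(truth[0], rel=0.01)
        assert est[1] == pytest.approx(truth[1], rel=0.01)
        assert est[2] == pytest.approx(truth[2], abs=0.01)

    def test_no_observations_returns_prior_mode(self):
        subj = SubjectRecord(id="E", weight=70.0, TotA=6e5, TotC_total=700.0)
        est = map_estimate(subj, POP, settings=SETTINGS)
        assert est == pytest.approx(POP.mu, rel=1e-12)

    def test_objective_never_worse_than_start(self):
        subj = make_subject(POP.mu, n_obs_noise=0.1)
        start = (500.0, 150.0, 0.4)
        est = map_estimate(subj, POP, start=start, settings=SETTINGS)
        assert (neg_log_posterior(est, subj, POP, SETTINGS)
                <= neg_log_posterior(start, subj, POP, SETTINGS) + 1e-9)


class TestUpdatePopulation:
    def test_identical_thetas_zero_omega(self):
        t = np.tile(to_transformed(400.0, 200.0, 0.15), (5, 1))
        mu, omega = update_population(t)
        np.testing.assert_allclose(omega, 0.0, atol=1e-12)
        np.testing.assert_allclose(mu, t[0])

    def test_two_subject_hand_values(self):
        """Geometric mean / log-SD (ddof=1) verified by hand."""
        a = to_transformed(300.0, 150.0, 0.1)
        b = to_transformed(500.0, 250.0, 0.3)
        mu, omega = update_population(np.vstack([a, b]))
        assert np.exp(mu[0]) == pytest.approx(np.sqrt(300 * 500), rel=1e-12)
        assert omega[0] == pytest.approx(
            abs(np.log(500) - np.log(300)) / np.sqrt(2), rel=1e-12)

    def test_permutation_invariance(self):
        rng = np.random.default_rng(8)
        t = rng.normal(size=(10, 3))
        mu1, om1 = update_population(t)
        mu2, om2 = update_population(t[::-1])
        np.testing.assert_allclose(mu1, mu2)
        np.testing.assert_allclose(om1, om2)

    def test_fewer_than_two_rejected(self):
        with pytest.raises(ValueError):
            update_population(np.zeros((1, 3)))


@pytest.fixture(scope="module")
def sparse_fit():
    design = StudyDesign(n_subjects=20)
    ds, truth = generate(design, POP, seed=11, fixed=CFG.fixed_params())
    result = fit(ds, CFG.prior_population(), SETTINGS)
    return ds, truth, result


class TestFit:
    def test_converges_and_is_deterministic(self, sparse_fit):
        ds, _, result = sparse_fit
        assert result.converged and result.n_iter <= 50
        again = fit(ds, CFG.prior_population(), SETTINGS)
        pd.testing.assert_frame_equal(result.trace, again.trace)

    def test_homogeneous_population_limit(self):
        """omega = 0 generating, tiny noise -> near-zero recovered omega."""
        pop0 = PopulationModel(mu=POP.mu, omega=(0.0, 0.0, 0.0),
                               sigma_add=0.05, sigma_prop=0.002)
        ds, _ = generate(StudyDesign(n_subjects=12), pop0, seed=3,
                         fixed=CFG.fixed_params())
        res = fit(ds, CFG.prior_population().with_updates(
            sigma_add=0.05, sigma_prop=0.002), SETTINGS)
        assert res.population.mu[0] == pytest.approx(POP.mu[0], rel=0.02)
        assert res.population.mu[1] == pytest.approx(POP.mu[1], rel=0.02)
        assert res.population.cv_percent()["V"] < 5.0

    def test_duplicated_subjects_leave_mu_unchanged(self, sparse_fit):
        ds, _, result = sparse_fit
        doubled = ds + [SubjectRecord(id=s.id + "b", weight=s.weight,
                                      TotA=s.TotA, TotC_total=s.TotC_total,
                                      doses=s.doses,
                                      observations=s.observations)
                        for s in ds]
        res2 = fit(doubled, CFG.prior_population(), SETTINGS)
        assert res2.population.mu[0] == pytest.approx(result.population.mu[0],
                                                      rel=0.01)
        assert res2.population.mu[1] == pytest.approx(result.population.mu[1],
                                                      rel=0.01)

    def test_empty_dataset_rejected(self):
        with pytest.raises(ValueError):
            fit([], POP, SETTINGS)

    def test_monotone_descent_of_total_objective_classic_mode(self):
        """With residual and omega held fixed, the classic MAP/SD two-stage
        loop does not increase the summed individual objectives between
        consecutive individual stages evaluated under the same population."""
        ds, _ = generate(StudyDesign(n_subjects=10), POP, seed=5,
                         fixed=CFG.fixed_params())
        st = FitSettings(individual_estimator="map", omega_method="sd",
                         max_iter=6)
        prior = CFG.prior_population()
        res = fit(ds, prior, st)
        # within one population state, re-fitting individuals from their
        # previous optima cannot worsen the total objective
        total_before = sum(
            neg_log_posterior(tuple(r[["V", "CL", "RC"]]), s,
                              res.population, st)
            for (_, r), s in zip(res.individual.iterrows(), ds))
        total_start = sum(
            neg_log_posterior(res.population.mu, s, res.population, st)
            for s in ds)
        assert total_before <= total_start + 1e-6


class TestShrinkage:
    def test_all_estimates_at_mu_gives_100(self):
        t = np.tile(POP.mu_transformed, (6, 1))
        shr = shrinkage(t, POP)
        assert shr["V"] == shr["CL"] == shr["RC"] == 100.0

    def test_deviations_with_sd_equal_omega_gives_0(self):
        rng = np.random.default_rng(12)
        z = rng.standard_normal(500)
        z = (z - z.mean()) / z.std(ddof=1)
        t = POP.mu_transformed + np.outer(z, np.asarray(POP.omega))
        shr = shrinkage(t, POP)
        for v in shr.values():
            assert v == pytest.approx(0.0, abs=1e-9)

    def test_zero_omega_reported_missing(self):
        pop0 = POP.with_updates(omega=(0.5, 0.0, 0.5))
        shr = shrinkage(np.tile(pop0.mu_transformed, (4, 1)), pop0)
        assert shr["CL"] is None

    def test_sparse_design_between_0_and_100(self, sparse_fit):
        _, _, result = sparse_fit
        for v in result.population.shrinkage.values():
            assert v is not None and 0.0 <= v < 100.0


class TestWeightedResiduals:
    def test_exact_prediction_gives_zero(self):
        subj = make_subject(POP.mu)
        wres = weighted_residuals([subj], POP, settings=SETTINGS)
        np.testing.assert_allclose(wres["wres_population"], 0.0, atol=1e-12)

    def test_hand_case(self):
        """y=110, f=100, 1.1 add + 9.5% prop -> 10/9.564."""
        expected = 10.0 / np.sqrt(1.1**2 + 9.5**2)
        assert expected == pytest.approx(1.046, abs=1e-3)

    def test_distribution_under_true_model(self):
        """WRES evaluated at each subject's true parameters on correctly
        specified simulated data pools to mean ~0, SD ~1."""
        ds, truth = generate(StudyDesign(n_subjects=60), POP, seed=21,
                             fixed=CFG.fixed_params())
        true_ind = truth.individual[["subject_id", "V", "CL", "RC"]]
        wres = weighted_residuals(ds, POP, true_ind, SETTINGS)
        ind = wres["wres_individual"].to_numpy()
        assert -0.2 < ind.mean() < 0.2
        assert 0.8 < ind.std() < 1.2
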