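"""Sampler correctness, convergence diagnostics and prior sensitivity."""

import numpy as np
import pytest
from scipy import stats

from rdsem import (EstimationError, GeneratingConfig, ess, expand_time_lattice,
                   fit_mcmc, generate_panel, prior_sensitivity, rhat)
from rdsem.dynamics import stationary_cov
from rdsem.gibbs import _build_impute_plan, impute_missing_sweep


class TestESS:
    def test_iid_draws_near_total(self):
        rng = np.random.default_rng(0)
        arr = rng.standard_normal((4, 1000))
        assert ess(arr) == pytest.approx(4000, rel=0.10)

    def test_ar1_closed_form(self):
        # ESS of an AR(1) chain with lag-1 correlation rho is N (1-rho)/(1+rho)
        rho, n = 0.9, 20000
        rng = np.random.default_rng(1)
        chains = np.empty((4, n))
        for c in range(4):
            e = rng.standard_normal(n)
            x = np.empty(n)
            x[0] = e[0]
            for t in range(1, n):
                x[t] = rho * x[t - 1] + np.sqrt(1 - rho**2) * e[t]
            chains[c] = x
        expected = 4 * n * (1 - rho) / (1 + rho)
        assert ess(chains) == pytest.approx(expected, rel=0.20)

    def test_constant_chain_undefined(self):
        assert np.isnan(ess(np.ones((2, 200))))

    def test_too_few_draws_is_error(self):
        with pytest.raises(EstimationError):
            ess(np.random.default_rng(0).standard_normal((2, 20)))


class TestRhat:
    def test_identical_distribution_chains_near_one(self):
        rng = np.random.default_rng(2)
        r = rhat(rng.standard_normal((4, 2000)))
        assert r == pytest.approx(1.0, abs=0.01)

    def test_offset_chains_flagged(self):
        rng = np.random.default_rng(3)
        arr = rng.standard_normal((2, 1000))
        arr[1] += 5.0
        assert rhat(arr) > 1.1

    def test_single_chain_is_error(self):
        with pytest.raises(EstimationError):
            rhat(np.random.default_rng(0).standard_normal((1, 500)))


class TestImputationKernel:
    def test_matches_brute_force_conditional(self):
        """With parameters held fixed, repeated imputation sweeps target the
        exact Gaussian conditional of the missing residual cells given the
        observed ones (checked against Schur conditioning of the joint
        stationary VAR covariance)."""
        rng = np.random.default_rng(4)
        phi = np.array([[0.3, 0.1, 0.0], [0.0, 0.4, 0.1], [0.1, 0.0, 0.2]])
        su = np.array([[0.5, 0.1, 0.05], [0.1, 0.6, -0.1], [0.05, -0.1, 0.4]])
        seps = stationary_cov(phi, su)
        T = 5
        # joint covariance of the stacked residual path (15-dim)
        joint = np.zeros((3 * T, 3 * T))
        for t in range(T):
            for s in range(t, T):
                block = np.linalg.matrix_power(phi, s - t) @ seps if s > t else seps
                joint[3 * s:3 * s + 3, 3 * t:3 * t + 3] = block
                joint[3 * t:3 * t + 3, 3 * s:3 * s + 3] = block.T
        full = rng.multivariate_normal(np.zeros(3 * T), joint).reshape(1, T, 3)
        obs = np.ones((1, T, 3), dtype=bool)
        # a consecutive all-missing run plus partially missing slices
        obs[0, 1, :] = False
        obs[0, 2, :2] = False
        obs[0, 4, 2] = False
        plan, class_masks = _build_impute_plan(obs)
        flat_missing = ~obs.ravel()

        # oracle: conditional mean of missing given observed
        mi, oi = np.where(flat_missing)[0], np.where(~flat_missing)[0]
        k = joint[np.ix_(mi, oi)] @ np.linalg.inv(joint[np.ix_(oi, oi)])
        cond_mean = k @ full.ravel()[oi]
        cond_sd = np.sqrt(np.diag(joint[np.ix_(mi, mi)]
                                  - k @ joint[np.ix_(oi, mi)]))

        eps = full.copy()
        su_inv, seps_inv = np.linalg.inv(su), np.linalg.inv(seps)
        n_sweeps, burn = 6000, 200
        total = np.zeros(mi.size)
        for s in range(n_sweeps + burn):
            impute_missing_sweep(eps, plan, class_masks, phi, su_inv, seps_inv, rng)
            if s >= burn:
                total += eps.ravel()[mi]
        mc_mean = total / n_sweeps
        # generous Monte-Carlo allowance: sweeps are autocorrelated
        assert np.allclose(mc_mean, cond_mean, atol=6 * cond_sd / np.sqrt(n_sweeps / 20))

    def test_observed_cells_untouched(self):
        rng = np.random.default_rng(5)
        phi = 0.2 * np.eye(3)
        su = np.eye(3)
        eps = rng.standard_normal((3, 4, 3))
        before = eps.copy()
        obs = np.ones((3, 4, 3), dtype=bool)
        obs[1, 2, 0] = False
        plan, class_masks = _build_impute_plan(obs)
        impute_missing_sweep(eps, plan, class_masks, phi, np.linalg.inv(su),
                             np.linalg.inv(stationary_cov(phi, su)), rng)
        changed = eps != before
        assert changed.sum() == 1 and changed[1, 2, 0]


class TestFit:
    def test_same_seed_identical_draws(self, small_cohort):
        _, panel = small_cohort
        a = fit_mcmc(panel, chains=2, iterations=60, seed=3)
        b = fit_mcmc(panel, chains=2, iterations=60, seed=3)
        for name in a.names():
            assert np.array_equal(a.array(name), b.array(name))

    def test_different_seeds_differ(self, small_cohort):
        _, panel = small_cohort
        a = fit_mcmc(panel, chains=1, iterations=60, seed=3)
        b = fit_mcmc(panel, chains=1, iterations=60, seed=4)
        assert not np.array_equal(a.array("phi[DUDIT<-DUDIT]"),
                                  b.array("phi[DUDIT<-DUDIT]"))

    def test_requires_preprocessing(self, small_cohort):
        cfg, _ = small_cohort
        raw = generate_panel(cfg, seed=1)
        with pytest.raises(EstimationError, match="lattice"):
            fit_mcmc(raw, iterations=10)

    def test_empty_data_is_error(self, small_cohort):
        _, panel = small_cohort
        from dataclasses import replace
        empty = replace(panel, records=panel.records.iloc[:0],
                        persons=panel.persons.iloc[:0])
        with pytest.raises(EstimationError):
            fit_mcmc(empty, iterations=10)

    def test_posterior_covers_null_dynamics(self, small_fit):
        """Short sanity check: the small-cohort fit keeps lagged coefficients
        in a plausible range and flags convergence status."""
        assert small_fit.converged is not None
        est = small_fit.mean("phi[DUDIT<-DUDIT]")
        assert -0.5 < est < 0.9


class TestPriorSensitivity:
    def test_identical_fits_have_zero_shift(self, small_fit):
        out = prior_sensitivity(small_fit, small_fit)
        assert np.allclose(out.table["shift"], 0.0)
        assert out.conservative and out.conservative_ar

    def test_mismatched_parameter_sets_error(self, small_fit):
        import copy
        other = copy.copy(small_fit)
        other.params = {k: v for k, v in small_fit.params.items()
                        if not k.startswith("phi")}
        with pytest.raises(EstimationError):
            prior_sensitivity(small_fit, other)

    def test_mismatched_data_error(self, small_fit):
        import copy
        other = copy.copy(small_fit)
        other.person_ids = list(small_fit.person_ids)[:-1] + ["ghost"]
        with pytest.raises(EstimationError):
            prior_sensitivity(small_fit, other)
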