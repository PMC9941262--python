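"""Joint-model posterior: decomposition, samplers, summaries."""

import numpy as np
import pytest

from fajoint.hazard import SurvivalDesign, survival_loglik
from fajoint.joint import (GaussianPrior, JointConfig, fit_joint,
                           log_posterior, run_mcmc, summarize)
from fajoint.lme import _group
from fajoint.mcmc import ChainSet
from fajoint.simulate import default_truth, generate_cohort, \
    trajectory_ranef_cov
from fajoint.splines import SplineSpec, natural_cubic_basis
from fajoint.validate import RECOVERY_CONFIG, mufa_truth

SPEC = SplineSpec((0.25, 6.0), (1.0, 2.0, 4.0))


def _toy_data(n=6, seed=0):
    rng = np.random.default_rng(seed)
    ages = np.array([0.25, 0.5, 1, 2, 4, 6.0])
    ids = np.repeat([f"s{i}" for i in range(n)], len(ages))
    aa = np.tile(ages, n)
    beta = np.array([10.0, -2, 5, -9, 4])
    y = natural_cubic_basis(aa, SPEC) @ beta + rng.normal(0, 1, len(aa))
    T = rng.uniform(0.5, 6, n)
    delta = rng.binomial(1, 0.5, n).astype(float)
    W = rng.binomial(1, 0.4, (n, 2)).astype(float)
    design = SurvivalDesign.build(T, delta, W, order=7)
    groups = _group(ids, aa, y)
    return design, groups, beta


class TestLogPosterior:
    def test_flat_prior_no_ranef_decomposes_into_submodels(self):
        design, groups, beta = _toy_data()
        gamma = np.array([0.3, -0.2])
        rates = np.array([0.2, 0.1, 0.3])
        got = log_posterior(beta, 1.0, None, None, gamma, rates, 0.0,
                            design, groups, SPEC)
        # longitudinal piece: iid Gaussian loglik at the fixed curve
        ll_long = 0.0
        for _, a, y in groups:
            r = y - natural_cubic_basis(a, SPEC) @ beta
            ll_long += -0.5 * len(y) * np.log(2 * np.pi) - 0.5 * np.sum(r * r)
        ll_surv = survival_loglik(design, gamma, np.log(rates))
        assert abs(got - (ll_long + ll_surv)) < 1e-10

    def test_priors_add_exactly(self):
        design, groups, beta = _toy_data()
        gamma = np.array([0.3, -0.2])
        rates = np.array([0.2, 0.1, 0.3])
        priors = {"alpha": GaussianPrior(np.zeros(1), np.ones(1))}
        flat = log_posterior(beta, 1.0, None, None, gamma, rates, 0.1,
                             design, groups, SPEC)
        with_p = log_posterior(beta, 1.0, None, None, gamma, rates, 0.1,
                               design, groups, SPEC, priors)
        assert np.isclose(with_p - flat, priors["alpha"].logpdf(0.1))

    def test_out_of_support_is_minus_inf(self):
        design, groups, beta = _toy_data()
        assert log_posterior(beta, -1.0, None, None, np.zeros(2),
                             [0.1] * 3, 0.0, design, groups, SPEC) == -np.inf
        assert log_posterior(beta, 1.0, None, None, np.zeros(2),
                             [0.1, -0.1, 0.1], 0.0, design, groups,
                             SPEC) == -np.inf

    def test_finite_over_prior_draws_on_toy(self, rng):
        # support check: the posterior is finite across prior draws
        design, groups, beta = _toy_data(n=8, seed=2)
        for _ in range(200):
            g = rng.normal(0, 2, 2)
            r = np.exp(rng.normal(-2, 1, 3))
            a = rng.normal(0, 1)
            b = rng.normal(0, 0.5, (design.n, 5))
            val = log_posterior(beta, np.exp(rng.normal(0, 0.5)),
                                np.eye(5), b, g, r, a, design, groups, SPEC)
            assert np.isfinite(val)


class TestSummarize:
    def _chains(self, alpha_draws):
        m, n = 3, len(alpha_draws) // 3
        draws = np.asarray(alpha_draws, float).reshape(m, n, 1)
        return ChainSet(draws=draws, burn_in=0, param_names=["alpha"],
                        seeds=(1, 2, 3), accept_rates=np.full(3, 0.3))

    def test_zero_draws_give_unit_hazard_ratio(self):
        with pytest.warns(UserWarning):  # zero within-chain variance
            s = summarize(self._chains(np.zeros(300)), "mufa", "ia", False)
        assert s.hr == 1.0 and s.hr_ci == (1.0, 1.0)

    def test_exp_of_mean_alpha(self, rng):
        draws = rng.normal(0.3784, 1e-6, 300)
        s = summarize(self._chains(draws), "mufa", "ia", False)
        assert abs(s.hr - 1.46) < 0.005

    def test_hr_per_two_units_is_square(self, rng):
        draws = rng.normal(-0.3, 0.05, 300)
        s = summarize(self._chains(draws), "mufa", "ia", False)
        hr2 = np.exp(2 * draws.reshape(3, 100).mean())
        assert np.isclose(hr2, s.hr ** 2)

    def test_unconverged_requires_override(self, rng):
        bad = np.concatenate([rng.normal(0, 1, 100), rng.normal(0, 1, 100),
                              rng.normal(8, 1, 100)])
        with pytest.raises(RuntimeError):
            summarize(self._chains(bad), "mufa", "ia", False)
        s = summarize(self._chains(bad), "mufa", "ia", False, override=True)
        assert not s.converged


class TestFitJoint:
    def test_marginal_fit_with_knot_selection_smoke(self):
        truth = mufa_truth(0.0)
        ch, rec = generate_cohort(truth, 250, seed=77)
        cfg = JointConfig(mode="marginal", n_iter=400, burn_in=200, seed=5,
                          knots="select", ranef="diagonal", quad_order=5)
        s = fit_joint(ch, rec, "mufa", outcome="ia", config=cfg)
        assert s.knot_table is not None and len(s.knot_table) == 4
        assert 0.2 < s.hr < 5.0
        assert s.hr_ci[0] <= s.hr <= s.hr_ci[1]

    def test_deterministic_given_seed(self):
        truth = mufa_truth(0.0)
        ch, rec = generate_cohort(truth, 200, seed=78)
        cfg = JointConfig(mode="marginal", n_iter=200, burn_in=100, seed=9,
                          knots="fixed", spline_spec=truth.spec,
                          ranef="diagonal", quad_order=5)
        s1 = fit_joint(ch, rec, "mufa", outcome="ia", config=cfg)
        s2 = fit_joint(ch, rec, "mufa", outcome="ia", config=cfg)
        assert np.array_equal(s1.chains.draws, s2.chains.draws)

    def test_energy_effect_separates_from_null_density(self):
        # density has no effect but energy does: the density CI covers 1
        # while the energy CI excludes 1
        truth = default_truth(
            assoc_process="density", assoc_coef=0.0,
            energy_assoc_coef=np.log(4.0),
            baseline_rates=np.array([0.03, 0.03, 0.03]))
        ch, rec = generate_cohort(truth, 500, seed=91)
        cfg = JointConfig(seed=3, spline_spec=truth.spec, **RECOVERY_CONFIG)
        s = fit_joint(ch, rec, "total_fat", outcome="ia",
                      energy_adjusted=True, config=cfg)
        assert s.hr_ci[0] <= 1.0 <= s.hr_ci[1]
        assert s.energy_hr_ci[0] > 1.0

    def test_full_mode_recovers_alpha_within_2_sd(self):
        import dataclasses

        alpha = -0.5
        truth = dataclasses.replace(
            mufa_truth(np.log(0.63)), assoc_coef=alpha,
            baseline_rates=np.array([0.8011, 0.7711, 0.6006]) * 8)
        ch, rec = generate_cohort(truth, 150, seed=5)
        cfg = JointConfig(mode="full", n_iter=2000, burn_in=1000, seed=3,
                          knots="fixed", spline_spec=truth.spec,
                          ranef="diagonal", quad_order=5)
        s = fit_joint(ch, rec, "mufa", outcome="ia", config=cfg)
        a = s.chains.flat("alpha")
        assert abs(a.mean() - alpha) < 2 * a.std()

    def test_full_mode_rejects_two_processes(self, small_cohort):
        _, ch, rec = small_cohort
        cfg = JointConfig(mode="full", n_iter=100, burn_in=50)
        with pytest.raises(NotImplementedError):
            fit_joint(ch, rec, "total_fat", outcome="ia",
                      energy_adjusted=True, config=cfg)


class TestRunMcmc:
    def test_chainset_layout_and_determinism(self):
        target = lambda x: -0.5 * float(x @ x)
        inits = [np.zeros(2), np.ones(2), -np.ones(2)]
        cs1 = run_mcmc(target, inits, 300, 100, [1, 2, 3], ["a", "b"])
        cs2 = run_mcmc(target, inits, 300, 100, [1, 2, 3], ["a", "b"])
        assert cs1.draws.shape == (3, 300, 2)
        assert np.array_equal(cs1.draws, cs2.draws)
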