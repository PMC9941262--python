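"""Cox screening: partial likelihood, interaction test, FDR step-up."""

import numpy as np
import pandas as pd
import pytest

from fajoint.cox import (cox_ph, early_intake_screen, fdr_step_up,
                         interaction_screen)
from fajoint.simulate import default_truth, generate_cohort


def _breslow_loglik(beta, times, status, X):
    """Hand-written Breslow partial log-likelihood (test oracle)."""
    eta = X @ beta
    ll = 0.0
    for i in np.where(status == 1)[0]:
        risk = times >= times[i]
        ll += eta[i] - np.log(np.sum(np.exp(eta[risk])))
    return ll


class TestCoxPH:
    def test_three_subject_analytic_estimate(self):
        # score equation -2 e^{2 beta} + 1 = 0  =>  beta = -(1/2) ln 2
        fit = cox_ph([1, 2, 3], [1, 1, 0], np.array([[1.0], [0.0], [1.0]]))
        assert abs(fit.coef[0] + 0.5 * np.log(2)) < 1e-6

    def test_estimate_maximises_hand_partial_likelihood(self, rng):
        n = 60
        X = rng.normal(size=(n, 2))
        T = rng.exponential(1 / np.exp(X @ [0.5, -0.3]))
        status = (T < np.median(T) * 1.5).astype(float)
        fit = cox_ph(T, status, X)
        eps = 1e-5
        for j in range(2):
            e = np.zeros(2)
            e[j] = eps
            grad = (_breslow_loglik(fit.coef + e, T, status, X)
                    - _breslow_loglik(fit.coef - e, T, status, X)) / (2 * eps)
            assert abs(grad) < 1e-4

    def test_constant_covariate_zero_with_infinite_variance(self):
        X = np.array([[1.0, 1.0], [0.0, 1.0], [1.0, 1.0]])
        fit = cox_ph([1, 2, 3], [1, 1, 0], X, names=["x", "const"])
        assert fit.coef[1] == 0.0 and np.isinf(fit.se[1])

    def test_all_constant_rejected(self):
        with pytest.raises(ValueError):
            cox_ph([1, 2, 3], [1, 1, 0], np.ones((3, 1)))

    def test_no_events_rejected(self):
        with pytest.raises(ValueError):
            cox_ph([1, 2, 3], [0, 0, 0], np.array([[1.0], [0.0], [1.0]]))

    def test_recovers_truth_at_n2000(self, rng):
        n = 2000
        X = np.column_stack([rng.binomial(1, 0.5, n),
                             rng.normal(size=n)]).astype(float)
        beta = np.array([0.6, -0.4])
        T = rng.exponential(1 / (0.1 * np.exp(X @ beta)))
        C = rng.uniform(0, 8, n)
        status = (T <= C).astype(float)
        fit = cox_ph(np.minimum(T, C), status, X)
        assert np.all(np.abs(fit.coef - beta) < 3 * fit.se)

    def test_wald_ci_and_p_consistent(self, rng):
        n = 500
        X = rng.normal(size=(n, 1))
        T = rng.exponential(1 / np.exp(0.3 * X[:, 0]))
        fit = cox_ph(T, np.ones(n), X)
        s = fit.summary()
        excludes_one = (s.ci_low > 1) | (s.ci_high < 1)
        assert ((s.p < 0.05) == excludes_one).all()


class TestInteractionScreen:
    def test_power_against_strong_interaction(self):
        # product log-HR 1.0 at n=2000: detected in >= 80% of replicates
        hits, reps = 0, 10
        for r in range(reps):
            rng = np.random.default_rng(500 + r)
            truth = default_truth(baseline_rates=np.array([0.03] * 3))
            ch, rec = generate_cohort(truth, 2000, seed=600 + r)
            x = rec[rec.age.isin([0.25, 0.5])].groupby("child_id").apply(
                lambda g: (g.total_fat / g.energy_mj).mean(),
                include_groups=False)
            xv = ch.child_id.map(x).fillna(x.mean()).to_numpy()
            bf = ch.breastfed_at_3mo.to_numpy(float)
            eta = 1.0 * bf * (xv - xv.mean())
            T = rng.exponential(1 / (0.05 * np.exp(eta)))
            status = (T <= 6).astype(float)
            ch2 = ch.copy()
            ch2["ia_status"] = status
            ch2["ia_age"] = np.where(status == 1, np.minimum(T, 6), np.nan)
            ch2["censor_age"] = 6.0
            p, _ = interaction_screen(ch2, rec, "total_fat")
            hits += p < 0.05
        assert hits >= 0.8 * reps

    def test_degenerate_product_column_rejected(self, small_cohort):
        _, ch, rec = small_cohort
        ch2 = ch.copy()
        ch2["breastfed_at_3mo"] = False
        with pytest.raises(ValueError):
            interaction_screen(ch2, rec, "total_fat")


class TestEarlyIntakeScreen:
    def test_runs_on_synthetic_cohort(self, small_cohort):
        _, ch, rec = small_cohort
        fit = early_intake_screen(ch, rec, "total_fat", outcome="ia")
        s = fit.summary()
        assert "early_intake" in s.index
        assert np.isfinite(s.loc["early_intake", "p"])


def _bh_oracle(p, q):
    """Hand-rolled Benjamini-Hochberg step-up (test oracle)."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p)
    k = 0
    for i, idx in enumerate(order, start=1):
        if p[idx] <= i * q / m:
            k = i
    reject = np.zeros(m, dtype=bool)
    reject[order[:k]] = True
    return reject


class TestFDR:
    def test_hand_worked_example(self):
        p = [0.001, 0.01, 0.03, 0.04, 0.2]
        got = fdr_step_up(p, 0.05)
        assert list(got) == [True, True, True, True, False]

    def test_all_ones_rejects_nothing(self):
        assert not fdr_step_up(np.ones(10)).any()

    def test_permutation_equivariance(self, rng):
        p = rng.uniform(size=12)
        perm = rng.permutation(12)
        assert np.array_equal(fdr_step_up(p)[perm], fdr_step_up(p[perm]))

    def test_matches_oracle_and_monotone_over_random_vectors(self, rng):
        for _ in range(1000):
            m = rng.integers(3, 25)
            p = np.round(rng.uniform(size=m), 3)
            got = fdr_step_up(p)
            assert np.array_equal(got, _bh_oracle(p, 0.05))
            # lowering one p-value never shrinks the rejection set
            j = rng.integers(m)
            p2 = p.copy()
            p2[j] *= rng.uniform()
            assert fdr_step_up(p2)[got].all()

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            fdr_step_up([0.1, 1.2])
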