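"""Synthetic cohort generator: determinism, study-condition calibration,
event-time sampling, and record invariants."""

import numpy as np
import pandas as pd
import pytest

from fajoint.hazard import piecewise_cumhaz
from fajoint.simulate import (SCHEDULE, SyntheticTruth, default_truth,
                              generate_cohort, generate_progression_cohort,
                              simulate_event_time, trajectory_ranef_cov)
from fajoint.splines import natural_cubic_basis
from fajoint.variables import LC_N3_COMPONENTS


class TestSimulateEventTime:
    def test_exponential_closed_form(self):
        H = lambda t: 0.7 * t
        assert abs(simulate_event_time(H, np.exp(-0.7)) - 1.0) < 1e-7

    def test_piecewise_exponential_quantile(self):
        rates, cps = [0.3, 0.6, 0.2], (1.99, 3.99)
        H = lambda t: piecewise_cumhaz(t, rates, cps)
        for u in (0.9, 0.5, 0.31):
            t = simulate_event_time(H, u)
            # analytic inverse: H(t) = -log u, solved segment by segment
            target = -np.log(u)
            edges = [0.0, 1.99, 3.99, np.inf]
            Hc = [0.0, 0.3 * 1.99, 0.3 * 1.99 + 0.6 * 2.0]
            k = max(i for i in range(3) if Hc[i] <= target)
            expect = edges[k] + (target - Hc[k]) / rates[k]
            assert abs(t - expect) < 1e-6

    def test_u_near_one_gives_small_time(self):
        assert simulate_event_time(lambda t: 2 * t, 1 - 1e-9) < 1e-6

    def test_beyond_horizon_is_inf(self):
        assert simulate_event_time(lambda t: 0.001 * t, 0.1) == np.inf

    def test_decreasing_hazard_detected(self):
        with pytest.raises(ValueError):
            simulate_event_time(lambda t: -t, 0.5)
        with pytest.raises(ValueError):
            simulate_event_time(lambda t: t, 1.5)


class TestGenerateCohort:
    def test_same_seed_reproduces_byte_for_byte(self):
        truth = default_truth()
        c1, r1 = generate_cohort(truth, 300, seed=9, all_variables=True)
        c2, r2 = generate_cohort(truth, 300, seed=9, all_variables=True)
        assert c1.to_csv() == c2.to_csv()
        assert r1.to_csv() == r2.to_csv()

    def test_null_model_matches_exponential_incidence(self):
        # alpha=0, gamma=0, constant baseline, no dropout:
        # 6-year incidence = 1 - exp(-6 lambda)
        lam = 0.02
        truth = default_truth(assoc_coef=0.0,
                              cov_log_hr=np.zeros(3),
                              baseline_rates=np.full(3, lam),
                              dropout_hazard=1e-9)
        ch, _ = generate_cohort(truth, 2000, seed=11)
        expect = 1 - np.exp(-6 * lam)
        se = np.sqrt(expect * (1 - expect) / 2000)
        assert abs(ch.ia_status.mean() - expect) < 3.5 * se

    def test_covariate_prevalences(self, small_cohort):
        _, ch, _ = small_cohort
        n = len(ch)
        for col, level, p in [("sex", "male", 0.531),
                              ("hla_risk", "high", 0.196),
                              ("familial_diabetes", "yes", 0.059)]:
            obs = (ch[col] == level).mean()
            assert abs(obs - p) < 3.5 * np.sqrt(p * (1 - p) / n)

    def test_study_incidences_and_dropout(self):
        ch, rec = generate_cohort(default_truth(), 6000, seed=21)
        assert abs(ch.ia_status.mean() - 0.044) < 0.010
        assert abs(ch.t1d_status.mean() - 0.017) < 0.006
        no_event = ch.ia_status == 0
        for a, p in [(1.0, 0.06), (2.0, 0.14), (6.0, 0.35)]:
            obs = ((ch.censor_age < a) & no_event).mean()
            assert abs(obs - p) < 0.03
        assert abs(rec.n_days.sum() / len(ch) - 14.3) < 1.5

    def test_survival_curve_matches_piecewise_exponential(self):
        # alpha=0, gamma=0, no censoring: empirical survival vs closed form
        rates = np.array([0.05, 0.02, 0.08])
        truth = default_truth(assoc_coef=0.0, cov_log_hr=np.zeros(3),
                              baseline_rates=rates, dropout_hazard=1e-9)
        ch, _ = generate_cohort(truth, 3000, seed=31)
        t_obs = np.where(ch.ia_status == 1, ch.ia_age, np.inf)
        for t in (1.0, 2.0, 3.0, 5.0):
            S = np.exp(-piecewise_cumhaz(t, rates))
            emp = (t_obs > t).mean()
            assert abs(emp - S) < 3.5 * np.sqrt(S * (1 - S) / 3000)

    def test_mean_intake_tracks_latent_curve(self, small_cohort):
        truth, _, rec = small_cohort
        for age in (0.25, 1.0, 4.0):
            latent = float(natural_cubic_basis(age, truth.spec)
                           @ truth.fixed_spline_coefs)
            obs = rec.loc[rec.age == age, "total_fat"].mean()
            assert abs(obs - latent) < 1.0

    def test_record_invariants(self, small_cohort):
        _, ch, rec = small_cohort
        assert (rec.energy_mj > 0).all()
        assert rec.n_days.isin([1, 2, 3]).all()
        num = rec.select_dtypes("number")
        assert (num.drop(columns=["age"]) >= 0).all().all()
        # named fatty acids never exceed their parent class
        for comp, parent in [("myristic_acid", "sfa"),
                             ("palmitic_acid", "sfa"),
                             ("linoleic_acid", "n6_pufa"),
                             ("arachidonic_acid", "n6_pufa"),
                             ("alpha_linolenic_acid", "n3_pufa")]:
            assert (rec[comp] <= rec[parent] + 1e-12).all()
        lc = rec[list(LC_N3_COMPONENTS)].sum(axis=1)
        assert np.allclose(lc, rec["lc_n3_pufa"], rtol=1e-9)

    def test_event_age_ordering(self, small_cohort):
        _, ch, _ = small_cohort
        both = ch.dropna(subset=["ia_age", "t1d_age"])
        assert (both.ia_age <= both.t1d_age + 1e-12).all()
        assert ((ch.censor_age > 0) & (ch.censor_age <= 6)).all()

    def test_invalid_parameters_rejected(self):
        bad = np.array([[1.0, 2.0], [2.0, 1.0]])  # indefinite
        with pytest.raises(ValueError):
            SyntheticTruth(ranef_cov=np.pad(bad, (0, 3)) - 0.5 * np.eye(5))
        with pytest.raises(ValueError):
            generate_cohort(default_truth(), 0)
        with pytest.raises(ValueError):
            generate_cohort(default_truth(), 10, schedule=[])

    def test_trajectory_ranef_cov_anchors(self):
        truth = default_truth()
        G = trajectory_ranef_cov(truth.spec, sd=2.0, corr=0.5)
        B = natural_cubic_basis(np.array([0.25, 1, 2, 4, 6.0]), truth.spec)
        V = B @ G @ B.T
        assert np.allclose(np.sqrt(np.diag(V)), 2.0, atol=1e-8)


class TestProgressionCohort:
    def test_seroconversion_age_distribution(self):
        ch, rec = generate_progression_cohort(default_truth(), 3000, seed=41)
        q = np.percentile(ch.sc_age, [25, 50, 75])
        assert abs(q[1] - 1.9) < 0.2
        assert 0.9 < q[0] < 1.5 and 2.8 < q[2] < 4.2
        assert ((ch.t1d_age.dropna() <= 6 + 1e-9)).all()

    def test_records_cover_pre_and_post_seroconversion(self):
        ch, rec = generate_progression_cohort(default_truth(), 200, seed=5)
        merged = rec.merge(ch[["child_id", "sc_age"]], on="child_id")
        has_post = merged[merged.age >= merged.sc_age].child_id.nunique()
        assert has_post > 190
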