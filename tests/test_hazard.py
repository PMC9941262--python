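"""Piecewise-constant baseline hazard, quadrature survival likelihood, and
the piecewise-exponential submodel fit."""

import numpy as np
from scipy.integrate import simpson
import pytest

from fajoint.hazard import (SurvivalDesign, piecewise_cumhaz,
                            piecewise_exponential_fit, quadrature_grid,
                            survival_loglik)
from fajoint.splines import SplineSpec, natural_cubic_basis

CPS = (1.99, 3.99)


class TestPiecewiseCumhaz:
    def test_hand_integration_example(self):
        # 1*1.99 + 2*2.00 + 3*1.01 = 9.02
        assert np.isclose(piecewise_cumhaz(5.0, [1, 2, 3], CPS), 9.02)

    def test_constant_rates(self):
        assert np.isclose(piecewise_cumhaz(6.0, [0.3, 0.3, 0.3], CPS), 1.8)

    def test_zero_at_origin(self):
        assert piecewise_cumhaz(0.0, [1, 2, 3], CPS) == 0.0

    def test_linearity_in_rates(self):
        t = np.array([0.5, 2.5, 5.5])
        H1 = piecewise_cumhaz(t, [0.1, 0.2, 0.3], CPS)
        H2 = piecewise_cumhaz(t, [0.3, 0.6, 0.9], CPS)
        assert np.allclose(H2, 3 * H1)

    def test_nonpositive_rate_rejected(self):
        with pytest.raises(ValueError):
            piecewise_cumhaz(1.0, [1, 0, 3], CPS)


def _pwe_loglik(T, delta, W, gamma, rates):
    """Closed-form piecewise-exponential log-likelihood (test oracle)."""
    T = np.asarray(T, float)
    lin = np.asarray(W, float) @ np.asarray(gamma, float)
    edges = np.array([0.0, *CPS, np.inf])
    seg = np.clip(np.searchsorted(edges, T, side="right") - 1, 0, 2)
    log_h = np.log(np.asarray(rates, float))[seg] + lin
    H0 = np.array([piecewise_cumhaz(t, rates, CPS) for t in T])
    return float(np.sum(delta * log_h) - np.sum(np.exp(lin) * H0))


class TestSurvivalLoglik:
    def _toy(self):
        T = np.array([0.8, 2.5, 5.0])
        delta = np.array([1.0, 0.0, 1.0])
        W = np.array([[1.0, 0.0], [0.0, 1.0], [1.0, 1.0]])
        return SurvivalDesign.build(T, delta, W, CPS, order=15), T, delta, W

    def test_no_association_matches_closed_form(self):
        design, T, delta, W = self._toy()
        gamma = np.array([0.4, -0.3])
        rates = np.array([0.2, 0.1, 0.3])
        got = survival_loglik(design, gamma, np.log(rates))
        assert abs(got - _pwe_loglik(T, delta, W, gamma, rates)) < 1e-10

    def test_association_matches_trapezoid_oracle(self):
        # current-value association on a smooth spline trajectory;
        # reference integral by fine trapezoid refinement
        design, T, delta, W = self._toy()
        spec = SplineSpec((0.25, 6.0), (1.0, 2.0, 4.0))
        coefs = np.array([[10, -2, 5, -9, 4.0],
                          [12, -3, 6, -10, 4.5],
                          [9, -1, 4, -8, 3.5]])
        alpha, gamma = -0.3, np.array([0.4, -0.3])
        rates = np.array([0.2, 0.1, 0.3])
        B_nodes = natural_cubic_basis(design.nodes.ravel(), spec
                                      ).reshape(3, -1, 5)
        B_event = natural_cubic_basis(T, spec)
        assoc_nodes = alpha * np.einsum("nqk,nk->nq", B_nodes, coefs)
        assoc_event = alpha * np.einsum("nk,nk->n", B_event, coefs)
        got = survival_loglik(design, gamma, np.log(rates), assoc_nodes,
                              assoc_event)
        # oracle: trapezoid with 2**14 points per subject
        lin = W @ gamma
        edges = np.array([0.0, *CPS, np.inf])
        seg_T = np.clip(np.searchsorted(edges, T, side="right") - 1, 0, 2)
        ref = 0.0
        for i in range(3):
            s = np.linspace(0, T[i], 2 ** 14 + 1)
            m = natural_cubic_basis(s, spec) @ coefs[i]
            seg = np.clip(np.searchsorted(edges, s, side="right") - 1, 0, 2)
            h = rates[seg] * np.exp(lin[i] + alpha * m)
            ref += delta[i] * (np.log(rates[seg_T[i]]) + lin[i]
                               + assoc_event[i]) - simpson(h, x=s)
        assert abs(got - ref) < 1e-6

    def test_quadrature_error_decreases_with_order(self):
        _, T, delta, W = self._toy()
        spec = SplineSpec((0.25, 6.0), (1.0, 2.0, 4.0))
        coefs = np.array([[10, -2, 5, -9, 4.0],
                          [12, -3, 6, -10, 4.5],
                          [9, -1, 4, -8, 3.5]])
        alpha, gamma = -0.3, np.array([0.4, -0.3])
        rates = np.array([0.2, 0.1, 0.3])

        def loglik_at(order):
            design = SurvivalDesign.build(T, delta, W, CPS, order=order)
            B_nodes = natural_cubic_basis(design.nodes.ravel(), spec
                                          ).reshape(3, -1, 5)
            B_event = natural_cubic_basis(T, spec)
            return survival_loglik(
                design, gamma, np.log(rates),
                alpha * np.einsum("nqk,nk->nq", B_nodes, coefs),
                alpha * np.einsum("nk,nk->n", B_event, coefs))

        ref = loglik_at(40)
        errs = [abs(loglik_at(o) - ref) for o in (3, 5, 9, 15)]
        assert all(a >= b - 1e-14 for a, b in zip(errs, errs[1:]))
        # convergence is algebraic (the spline knots sit inside the baseline
        # segments), but order 15 is comfortably below the 1e-6 oracle band
        assert errs[-1] < 1e-6

    def test_low_order_rejected(self):
        with pytest.raises(ValueError):
            quadrature_grid(np.array([1.0]), CPS, order=2)


class TestPiecewiseExponentialFit:
    def test_recovers_truth_within_3_se(self, rng):
        n = 4000
        W = rng.binomial(1, 0.4, (n, 2)).astype(float)
        gamma = np.array([0.5, -0.4])
        rates = np.array([0.05, 0.08, 0.03])
        # inverse-cdf simulation with covariates
        u = rng.random(n)
        target = -np.log(u) / np.exp(W @ gamma)
        T = np.empty(n)
        for i in range(n):
            grid = np.linspace(1e-6, 12, 4000)
            H = piecewise_cumhaz(grid, rates, CPS)
            T[i] = grid[np.searchsorted(H, target[i])] \
                if H[-1] > target[i] else 12.0
        delta = (T < 6.0).astype(float)
        T = np.minimum(T, 6.0)
        g, lr, cov = piecewise_exponential_fit(T, delta, W, CPS)
        se = np.sqrt(np.diag(cov))
        est = np.concatenate([g, lr])
        truth = np.concatenate([gamma, np.log(rates)])
        assert np.all(np.abs(est - truth) < 3.5 * se)
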