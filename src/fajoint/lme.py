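"""Longitudinal submodel: spline linear mixed-effects fit and BIC knot selection.

The intake trajectory model is

    y_ij = x(age_ij)' beta + x(age_ij)' b_i + eps_ij,
    b_i ~ MVN(0, G),  eps_ij ~ N(0, sigma2),

where ``x(age)`` is the natural cubic spline basis, so every child carries
subject-specific spline coefficients.  Fitting is maximum likelihood through
statsmodels' MixedLM; the marginal log-likelihood stored on the fit is
recomputed here by direct per-subject multivariate-normal evaluation so the
BIC convention (below) is explicit:

    BIC = -2 loglik + p log(n_obs),
    p = dim(beta) + free elements of G + 1 (residual variance).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .splines import SplineSpec, natural_cubic_basis, candidate_knot_sets

__all__ = ["LongitudinalFit", "fit_lme", "select_knots", "marginal_loglik"]


def _group(ids, ages, values):
    ids = np.asarray(ids)
    ages = np.asarray(ages, dtype=float)
    values = np.asarray(values, dtype=float)
    order = np.argsort(ids, kind="stable")
    ids, ages, values = ids[order], ages[order], values[order]
    uniq, starts = np.unique(ids, return_index=True)
    bounds = np.append(starts, ids.size)
    groups = [(uniq[k], ages[bounds[k]:bounds[k + 1]], values[bounds[k]:bounds[k + 1]])
              for k in range(uniq.size)]
    return groups


def marginal_loglik(beta, G, sigma2, groups, spec: SplineSpec) -> float:
    """Direct evaluation of the marginal Gaussian log-likelihood, summed over
    subjects: y_i ~ MVN(X_i beta, X_i G X_i' + sigma2 I)."""
    beta = np.asarray(beta, dtype=float)
    G = np.asarray(G, dtype=float)
    ll = 0.0
    for _, ages, y in groups:
        X = natural_cubic_basis(ages, spec)
        V = X @ G @ X.T + sigma2 * np.eye(len(y))
        r = y - X @ beta
        L = np.linalg.cholesky(V)
        z = np.linalg.solve(L, r)
        ll -= 0.5 * (len(y) * np.log(2 * np.pi) + 2 * np.sum(np.log(np.diag(L)))
                     + z @ z)
    return float(ll)


@dataclass
class LongitudinalFit:
    """ML estimate of the spline mixed model for one longitudinal process."""

    beta: np.ndarray
    beta_se: np.ndarray
    G: np.ndarray
    sigma2: float
    loglik: float
    bic: float
    n_obs: int
    n_subjects: int
    spec: SplineSpec
    ranef: str
    converged: bool
    _groups: list = field(repr=False, default_factory=list)

    @property
    def n_params(self) -> int:
        k = len(self.beta)
        g_free = k * (k + 1) // 2 if self.ranef == "full" else k
        return k + g_free + 1

    def empirical_bayes(self):
        """Posterior means and covariances of the random effects b_i.

        Returns ``(ids, b_hat (n_sub, k), V (n_sub, k, k))`` with
        b_hat_i = G X_i' V_i^{-1} (y_i - X_i beta) and
        V_i = G - G X_i' V_i^{-1} X_i G (the conditional covariance).
        """
        k = len(self.beta)
        ids, bhats, covs = [], [], []
        for gid, ages, y in self._groups:
            X = natural_cubic_basis(ages, self.spec)
            V = X @ self.G @ X.T + self.sigma2 * np.eye(len(y))
            GXt = self.G @ X.T
            sol = np.linalg.solve(V, np.column_stack([y - X @ self.beta, X @ self.G]))
            bhats.append(GXt @ sol[:, 0])
            covs.append(self.G - GXt @ sol[:, 1:])
            ids.append(gid)
        return np.asarray(ids), np.vstack(bhats), np.stack(covs)

    def predict(self, ages, b=None):
        X = natural_cubic_basis(np.asarray(ages, float), self.spec)
        coef = self.beta if b is None else self.beta + b
        return X @ coef


def _padded_arrays(groups, spec: SplineSpec):
    """Stack ragged per-subject data into masked (n, m_max, .) arrays."""
    n = len(groups)
    m_max = max(len(a) for _, a, _ in groups)
    k = spec.n_basis
    Y = np.zeros((n, m_max))
    M = np.zeros((n, m_max))
    B = np.zeros((n, m_max, k))
    for i, (_, ages, y) in enumerate(groups):
        m = len(y)
        Y[i, :m] = y
        M[i, :m] = 1.0
        B[i, :m] = natural_cubic_basis(ages, spec)
    return Y, M, B


def _loglik_padded(beta, G, sigma2, Y, M, B):
    """Marginal loglik via the matrix-inversion lemma on padded arrays."""
    n, m_max, k = B.shape
    r = (Y - B @ beta) * M
    Ginv = np.linalg.inv(G + 1e-12 * np.eye(k))
    BtB = np.matmul(B.transpose(0, 2, 1), B * M[:, :, None])  # (n, k, k)
    C = Ginv + BtB / sigma2
    sign, logdet_C = np.linalg.slogdet(C)
    sign_g, logdet_G = np.linalg.slogdet(G + 1e-12 * np.eye(k))
    Btr = np.einsum("nmk,nm->nk", B, r)
    sol = np.linalg.solve(C, Btr[..., None])[..., 0]
    quad = (np.sum(r * r, axis=1) - np.einsum("nk,nk->n", Btr, sol) / sigma2
            ) / sigma2
    n_obs_i = M.sum(axis=1)
    logdet_V = n_obs_i * np.log(sigma2) + logdet_G + logdet_C
    return float(-0.5 * np.sum(n_obs_i * np.log(2 * np.pi) + logdet_V + quad))


def _fit_em(groups, spec: SplineSpec, ranef: str, maxiter: int, tol: float):
    """Vectorised EM for the ML fit; monotone in the marginal loglik."""
    Y, M, B = _padded_arrays(groups, spec)
    n, m_max, k = B.shape
    N = M.sum()
    # start: pooled least squares, modest G
    X_all = B[M.astype(bool)]
    y_all = Y[M.astype(bool)]
    beta, *_ = np.linalg.lstsq(X_all, y_all, rcond=None)
    resid0 = y_all - X_all @ beta
    sigma2 = max(float(np.var(resid0)) / 2.0, 1e-8)
    G = np.eye(k) * max(float(np.var(resid0)) / 2.0, 1e-8)
    BtB = np.matmul(B.transpose(0, 2, 1), B * M[:, :, None])
    XtX_inv = np.linalg.inv(BtB.sum(axis=0))
    ll_old = -np.inf
    converged = False
    for it in range(maxiter):
        Ginv = np.linalg.inv(G + 1e-12 * np.eye(k))
        C = Ginv + BtB / sigma2
        r = (Y - B @ beta) * M
        Btr = np.einsum("nmk,nm->nk", B, r)
        V = np.linalg.inv(C)                       # (n, k, k) cond. covariance
        bhat = (V @ Btr[..., None])[..., 0] / sigma2
        # M-step with one pseudo-count of shrinkage: directions of G that do
        # not move the marginal covariance (near-null basis combinations)
        # are otherwise unidentified and drift along a likelihood ridge
        G = (np.einsum("ni,nj->ij", bhat, bhat) + V.sum(axis=0)
             + 1e-8 * np.eye(k)) / (n + 1)
        if ranef == "diagonal":
            G = np.diag(np.diag(G))
        fitted_b = np.einsum("nmk,nk->nm", B, bhat) * M
        beta = XtX_inv @ np.einsum("nmk,nm->k", B, (Y * M - fitted_b))
        r = (Y - B @ beta) * M
        resid = r - fitted_b
        tr_term = np.einsum("nkl,nlk->", V, BtB)
        sigma2 = max(float((np.sum(resid * resid) + tr_term) / N), 1e-10)
        if it % 10 == 9 or it == maxiter - 1:
            ll = _loglik_padded(beta, G, sigma2, Y, M, B)
            if abs(ll - ll_old) < tol * (1 + abs(ll)):
                converged = True
                break
            ll_old = ll
    G = 0.5 * (G + G.T)
    # fixed-effect covariance from the marginal GLS information
    Ginv = np.linalg.inv(G + 1e-12 * np.eye(k))
    C = Ginv + BtB / sigma2
    VinvB = (BtB - np.matmul(BtB, np.linalg.solve(C, BtB)) / sigma2) / sigma2
    beta_cov = np.linalg.inv(VinvB.sum(axis=0))
    return beta, G, sigma2, np.sqrt(np.diag(beta_cov)), converged


def _fit_statsmodels(groups, spec, ranef, maxiter):
    from statsmodels.regression.mixed_linear_model import MixedLM, MixedLMParams

    gid = np.concatenate([[g] * len(a) for g, a, _ in groups])
    all_ages = np.concatenate([a for _, a, _ in groups])
    y = np.concatenate([v for _, _, v in groups])
    X = natural_cubic_basis(all_ages, spec)
    model = MixedLM(y, X, groups=gid, exog_re=X)
    free = None
    if ranef == "diagonal":
        free = MixedLMParams.from_components(
            fe_params=np.ones(X.shape[1]), cov_re=np.eye(X.shape[1]))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = model.fit(reml=False, free=free, method="lbfgs", maxiter=maxiter)
    G = np.asarray(res.cov_re, dtype=float)
    return (np.asarray(res.fe_params, float), 0.5 * (G + G.T),
            float(res.scale), np.asarray(res.bse_fe, float),
            bool(getattr(res, "converged", True)))


def fit_lme(ids, ages, values, spec: SplineSpec, ranef: str = "full",
            maxiter: int = 2000, tol: float = 1e-6,
            engine: str = "em") -> LongitudinalFit:
    """Fit the natural-spline mixed model by maximum likelihood.

    Parameters
    ----------
    ids, ages, values : long-format longitudinal data (one row per record).
    spec : knot layout; the basis includes the intercept.
    ranef : "full" for an unstructured G, "diagonal" for independent
        subject-specific spline coefficients (more stable at small n).
    engine : "em" (vectorised EM, the default — each sweep increases the
        marginal likelihood) or "statsmodels" (MixedLM, kept as an
        independent route for cross-checking).
    """
    if ranef not in ("full", "diagonal"):
        raise ValueError(f"ranef must be 'full' or 'diagonal', got {ranef!r}")
    groups = _group(ids, ages, values)
    if len(groups) < 2:
        raise ValueError("need at least 2 subjects")
    if engine == "em":
        beta, G, sigma2, beta_se, converged = _fit_em(groups, spec, ranef,
                                                      maxiter, tol)
    elif engine == "statsmodels":
        beta, G, sigma2, beta_se, converged = _fit_statsmodels(
            groups, spec, ranef, maxiter)
    else:
        raise ValueError(f"unknown engine {engine!r}")
    loglik = marginal_loglik(beta, G, sigma2, groups, spec)
    k = len(beta)
    g_free = k * (k + 1) // 2 if ranef == "full" else k
    p = k + g_free + 1
    n_obs = sum(len(a) for _, a, _ in groups)
    bic = -2.0 * loglik + p * np.log(n_obs)
    return LongitudinalFit(
        beta=beta, beta_se=beta_se, G=G,
        sigma2=sigma2, loglik=loglik, bic=float(bic), n_obs=int(n_obs),
        n_subjects=len(groups), spec=spec, ranef=ranef, converged=converged,
        _groups=groups)


def select_knots(ids, ages, values, candidates=None, boundary=None,
                 ranef: str = "full", max_grid: int = 10
                 ) -> tuple[LongitudinalFit, pd.DataFrame]:
    """Fit every candidate internal-knot set and return the minimal-BIC fit.

    Candidates default to all feasible triples on the distinct observed-age
    grid (two distinct ages strictly outside each boundary knot, consecutive
    knots >= 1 year apart).  On a near-continuous time scale (more than
    ``max_grid`` distinct ages, as after re-expressing ages relative to
    seroconversion) the grid is first coarsened to evenly spaced quantiles so
    the enumeration stays finite.  Ties are broken toward the
    lexicographically earliest knot set; the returned table lists each
    candidate with its BIC.
    """
    ages_arr = np.asarray(ages, dtype=float)
    if boundary is None:
        boundary = (float(ages_arr.min()), float(ages_arr.max()))
    if candidates is None:
        grid = np.unique(ages_arr)
        if grid.size > max_grid:
            grid = np.unique(np.round(
                np.quantile(ages_arr, np.linspace(0, 1, max_grid)), 2))
        try:
            candidates = candidate_knot_sets(grid)
        except ValueError:
            # no feasible triple on this grid: fall back to three knots at
            # equally long intervals inside the boundary
            lo, hi = boundary
            fallback = tuple(np.round(np.linspace(lo, hi, 5)[1:4], 3))
            warnings.warn(f"no feasible knot triple on the observed-age "
                          f"grid; using equally spaced knots {fallback}")
            candidates = [fallback]
    if len(candidates) == 0:
        raise ValueError("no candidate knot sets supplied")
    rows, fits = [], {}
    for knots in sorted(candidates):
        try:
            fit = fit_lme(ids, ages, values,
                          SplineSpec(boundary, tuple(knots)), ranef=ranef)
        except Exception as exc:
            rows.append({"knots": tuple(knots), "bic": np.nan, "loglik": np.nan,
                         "converged": False, "error": str(exc)})
            continue
        fits[tuple(knots)] = fit
        rows.append({"knots": tuple(knots), "bic": fit.bic, "loglik": fit.loglik,
                     "converged": fit.converged, "error": ""})
    table = pd.DataFrame(rows)
    if not fits:
        raise RuntimeError("every candidate knot-set fit failed")
    best = min(fits, key=lambda k: (fits[k].bic, k))
    return fits[best], table
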