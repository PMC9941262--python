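"""Time-independent Cox screening of early (3-6 month) intake, the
breastfeeding-interaction test, and Benjamini-Hochberg FDR control.

The early-intake analysis treats the mean energy-adjusted intake over the
3- and 6-month records as a fixed baseline covariate in a Cox proportional
hazards model adjusted for sex, HLA risk and familial diabetes (Breslow tie
handling by default; the follow-up grid makes ties possible).  The
interaction screen adds breastfed-at-3-months and its product with the early
intake and Wald-tests the product term.  The joint-model test family (12 fat
variables x 2 adjustments x 3 outcomes = 72 tests) is corrected with the
FDR step-up procedure at the 0.05 level.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .nutrients import mean_early_intake
from .simulate import encode_covariates
from .variables import VARIABLES, compose_sum_variable, rescale_intake

log = logging.getLogger(__name__)

__all__ = ["CoxFit", "cox_ph", "early_intake_screen", "interaction_screen",
           "fdr_step_up"]


@dataclass
class CoxFit:
    """Partial-likelihood estimate with Wald inference per covariate."""

    names: list[str]
    coef: np.ndarray
    cov: np.ndarray
    loglik: float
    n_events: int

    @property
    def se(self) -> np.ndarray:
        return np.sqrt(np.diag(self.cov))

    def summary(self) -> pd.DataFrame:
        from scipy.stats import norm

        se = self.se
        with np.errstate(over="ignore", divide="ignore", invalid="ignore"):
            z = self.coef / se
            return pd.DataFrame({
                "coef": self.coef, "se": se,
                "hr": np.exp(self.coef),
                "ci_low": np.exp(self.coef - 1.959963984540054 * se),
                "ci_high": np.exp(self.coef + 1.959963984540054 * se),
                "p": 2 * norm.sf(np.abs(z)),
            }, index=self.names)


def cox_ph(times, status, covariates, names=None, ties: str = "breslow",
           maxiter: int = 25, gtol: float = 1e-8) -> CoxFit:
    """Cox proportional-hazards fit (statsmodels PHReg behind the surface).

    Raises on degenerate designs: a covariate with no variation among
    comparable subjects yields infinite variance, and monotone likelihoods
    (separation) surface as non-convergence naming the worst covariate.
    """
    import statsmodels.api as sm

    times = np.asarray(times, float)
    status = np.asarray(status, float)
    X = np.atleast_2d(np.asarray(covariates, float))
    if X.shape[0] != times.size:
        X = X.T
    if names is None:
        names = [f"x{j}" for j in range(X.shape[1])]
    if status.sum() < 1:
        raise ValueError("need at least one event")
    const = np.ptp(X, axis=0) == 0
    if const.all():
        raise ValueError("degenerate design: every covariate is constant")
    if const.any():
        # no information: coefficient 0 with infinite variance, flagged
        bad = [names[j] for j in np.where(const)[0]]
        log.warning("covariates with no variation get coef 0 and infinite "
                    "variance: %s", bad)
    keep = ~const
    mod = sm.PHReg(times, X[:, keep], status=status, ties=ties)
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = mod.fit(maxiter=maxiter, tol=gtol, disp=False)
    coef = np.zeros(X.shape[1])
    coef[keep] = np.asarray(res.params, float)
    cov = np.full((X.shape[1], X.shape[1]), np.inf)
    cov[np.ix_(keep, keep)] = np.asarray(res.cov_params(), float)
    if not np.all(np.isfinite(cov[np.ix_(keep, keep)])) or \
            np.any(np.abs(coef) > 15):
        worst = names[int(np.argmax(np.abs(coef)))]
        raise RuntimeError(
            f"monotone partial likelihood (separation), covariate {worst!r}")
    return CoxFit(names=list(names), coef=coef, cov=cov,
                  loglik=float(mod.loglike(np.asarray(res.params, float))),
                  n_events=int(status.sum()))


def _early_covariate(children: pd.DataFrame, records: pd.DataFrame,
                     variable, energy_adjusted: bool = True) -> pd.Series:
    if isinstance(variable, str):
        variable = VARIABLES[variable]
    rec = records.copy()
    if variable.is_sum and variable.name not in rec.columns:
        rec[variable.name] = compose_sum_variable(rec, variable)
    rec[variable.name] = rescale_intake(rec[variable.name].to_numpy(float),
                                        variable.unit)
    vals = {}
    for cid, grp in rec.groupby("child_id"):
        vals[cid] = mean_early_intake(grp, variable.name, energy_adjusted)
    return children["child_id"].map(vals)


def early_intake_screen(children: pd.DataFrame, records: pd.DataFrame,
                        variable, outcome: str = "ia",
                        energy_adjusted: bool = True,
                        ties: str = "breslow") -> CoxFit:
    """Cox model with mean 3-6-month intake as a time-independent covariate.

    Children with neither a 3- nor a 6-month record are excluded.
    """
    x = _early_covariate(children, records, variable, energy_adjusted)
    keep = x.notna().to_numpy()
    kids = children[keep]
    status = kids[f"{outcome}_status"].to_numpy(float)
    T = np.where(status == 1, kids[f"{outcome}_age"].to_numpy(float),
                 kids["censor_age"].to_numpy(float))
    W = encode_covariates(kids)
    X = np.column_stack([x[keep].to_numpy(float), W.to_numpy(float)])
    names = ["early_intake", *W.columns]
    return cox_ph(T, status, X, names, ties=ties)


def interaction_screen(children: pd.DataFrame, records: pd.DataFrame,
                       variable, outcome: str = "ia",
                       ties: str = "breslow"):
    """Wald p-value for breastfed-at-3-months x early-intake interaction.

    The model carries both main effects, the product term, and the standard
    adjustment covariates; returns ``(p_value, fit)``.
    """
    x = _early_covariate(children, records, variable, energy_adjusted=True)
    keep = x.notna().to_numpy()
    kids = children[keep]
    xv = x[keep].to_numpy(float)
    bf = kids["breastfed_at_3mo"].to_numpy(float)
    prod = bf * (xv - xv.mean())
    if np.ptp(prod) == 0:
        raise ValueError("degenerate design: interaction column is constant")
    status = kids[f"{outcome}_status"].to_numpy(float)
    T = np.where(status == 1, kids[f"{outcome}_age"].to_numpy(float),
                 kids["censor_age"].to_numpy(float))
    W = encode_covariates(kids)
    X = np.column_stack([xv, bf, prod, W.to_numpy(float)])
    names = ["early_intake", "breastfed_3mo", "breastfed_x_intake", *W.columns]
    fit = cox_ph(T, status, X, names, ties=ties)
    p = float(fit.summary().loc["breastfed_x_intake", "p"])
    return p, fit


def fdr_step_up(pvalues, q: float = 0.05) -> np.ndarray:
    """Benjamini-Hochberg step-up rejections at level ``q``, in input order.

    Sort ascending, find the largest i with p_(i) <= i q / m, reject all
    hypotheses with rank <= i.
    """
    from statsmodels.stats.multitest import multipletests

    p = np.asarray(pvalues, float)
    if p.size == 0:
        return np.zeros(0, dtype=bool)
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    reject, *_ = multipletests(p, alpha=q, method="fdr_bh")
    return np.asarray(reject, dtype=bool)
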