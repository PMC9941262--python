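"""Adaptive random-walk Metropolis sampling and convergence diagnostics.

The sampler is a block random-walk Metropolis with Haario-style diminishing
adaptation: during burn-in the proposal covariance tracks the empirical
covariance of the chain (scaled by 2.38^2/d) and a global step-size factor is
tuned toward the target acceptance rate; after burn-in the proposal is
frozen, so the post-burn-in draws target the exact posterior.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["adaptive_metropolis", "gelman_rubin", "ChainSet"]


class SamplerStalled(RuntimeError):
    """Raised when every proposal is rejected for a long stretch."""


def adaptive_metropolis(logpdf, x0, n_iter: int, seed: int,
                        burn_in: int | None = None,
                        init_scale: np.ndarray | float = 0.1,
                        target_accept: float = 0.3,
                        stall_limit: int = 1000):
    """Sample ``logpdf`` starting at ``x0``; returns ``(draws, accept_rate)``.

    ``draws`` has shape (n_iter, d) and includes the burn-in stretch
    (callers slice it off).  Adaptation happens only during burn-in.
    """
    rng = np.random.default_rng(seed)
    x = np.asarray(x0, dtype=float).copy()
    d = x.size
    if burn_in is None:
        burn_in = n_iter // 2
    scale = np.broadcast_to(np.asarray(init_scale, float), (d,)).copy()
    cov_chol = np.diag(scale)
    log_step = 0.0
    lp = logpdf(x)
    if not np.isfinite(lp):
        raise ValueError("initial point has non-finite log density")
    draws = np.empty((n_iter, d))
    n_accept = 0
    stall = 0
    mean = x.copy()
    cov = np.diag(scale ** 2)
    for it in range(n_iter):
        prop = x + np.exp(log_step) * (cov_chol @ rng.standard_normal(d))
        lp_prop = logpdf(prop)
        if np.log(rng.random()) < lp_prop - lp:
            x, lp = prop, lp_prop
            n_accept += 1
            stall = 0
        else:
            stall += 1
            if stall >= stall_limit:
                raise SamplerStalled(
                    f"no proposal accepted in {stall_limit} consecutive "
                    f"iterations (iteration {it})")
        draws[it] = x
        if it < burn_in:
            # diminishing adaptation of mean/covariance and step size
            w = 1.0 / (it + 2)
            diff = x - mean
            mean += w * diff
            cov = (1 - w) * cov + w * np.outer(diff, diff)
            accepted = stall == 0
            log_step += w * ((1.0 if accepted else 0.0) - target_accept)
            if it % 20 == 19:
                try:
                    cov_chol = np.linalg.cholesky(
                        (2.38 ** 2 / d) * cov + 1e-10 * np.eye(d))
                except np.linalg.LinAlgError:
                    pass
    return draws, n_accept / n_iter


def gelman_rubin(chains) -> float | np.ndarray:
    """Potential scale reduction factor.

    ``chains`` is (m, n) for one parameter or (m, n, d); requires m >= 2
    chains of equal post-burn-in length n >= 10.  Returns

        Rhat = sqrt( ((n-1)/n * W + B/n) / W )

    with W the mean within-chain variance and B/n the between-chain variance
    of the chain means.  Zero within-chain variance yields NaN with a warning.
    """
    arr = np.asarray(chains, dtype=float)
    squeeze = arr.ndim == 2
    if squeeze:
        arr = arr[:, :, None]
    m, n, d = arr.shape
    if m < 2 or n < 10:
        raise ValueError("need >= 2 chains of length >= 10")
    W = arr.var(axis=1, ddof=1).mean(axis=0)          # (d,)
    chain_means = arr.mean(axis=1)                    # (m, d)
    B_over_n = chain_means.var(axis=0, ddof=1)        # (d,)
    rhat = np.full(d, np.nan)
    ok = W > 0
    if not np.all(ok):
        warnings.warn("zero within-chain variance; Rhat undefined for some "
                      "parameters")
    rhat[ok] = np.sqrt(((n - 1) / n * W[ok] + B_over_n[ok]) / W[ok])
    return float(rhat[0]) if squeeze and d == 1 else rhat


@dataclass
class ChainSet:
    """Post-run MCMC output: 3 chains x iterations x parameters."""

    draws: np.ndarray                 # (m, n_iter, d) including burn-in
    burn_in: int
    param_names: list[str]
    seeds: tuple[int, ...]
    accept_rates: np.ndarray

    def __post_init__(self):
        m, n, d = self.draws.shape
        if d != len(self.param_names):
            raise ValueError("parameter names inconsistent with draws")
        if not (0 <= self.burn_in < n):
            raise ValueError("burn-in outside chain length")

    @property
    def posterior(self) -> np.ndarray:
        """(m, n_keep, d) post-burn-in draws."""
        return self.draws[:, self.burn_in:, :]

    def flat(self, name: str) -> np.ndarray:
        j = self.param_names.index(name)
        return self.posterior[:, :, j].ravel()

    def rhat(self) -> pd.Series:
        return pd.Series(gelman_rubin(self.posterior), index=self.param_names)

    def to_frame(self) -> pd.DataFrame:
        """Columnar chain archive: one row per draw with chain and iteration
        indices (post-burn-in only)."""
        m, n, d = self.posterior.shape
        out = pd.DataFrame(self.posterior.reshape(-1, d),
                           columns=self.param_names)
        out.insert(0, "iteration", np.tile(np.arange(n), m) + self.burn_in)
        out.insert(0, "chain", np.repeat(np.arange(m), n))
        return out

    def summary(self) -> pd.DataFrame:
        post = self.posterior
        flat = post.reshape(-1, post.shape[-1])
        return pd.DataFrame({
            "mean": flat.mean(axis=0),
            "sd": flat.std(axis=0, ddof=1),
            "q2.5": np.percentile(flat, 2.5, axis=0),
            "q97.5": np.percentile(flat, 97.5, axis=0),
            "rhat": gelman_rubin(post),
        }, index=self.param_names)
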