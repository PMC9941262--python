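"""Synthetic birth-cohort generator emulating the study design.

Children carry the cohort's covariate mix (53.1% male, 19.6% high-HLA,
5.9%/90.3%/3.8% familial diabetes yes/no/missing), attend food-record visits
at ages 0.25, 0.5, 1, 2, 3, 4, (5), 6 years, and drop out as an independent
exponential process calibrated to ~6/14/35% cumulative dropout by 1/2/6
years.  Each child has a latent intake trajectory

    m_i(t) = x(t)' (beta + b_i),   b_i ~ MVN(0, G),

observed with residual noise at retained visits, and an islet-autoimmunity
event time drawn from the proportional hazard with current-value association

    h_i(t) = h0(t) exp(gamma' w_i + alpha m_i(t)),

with piecewise-constant h0 (change points 1.99 / 3.99 y).  T1D follows a
second piecewise-exponential clock restarted at seroconversion.  Default
parameters reproduce J-shaped intake-by-age medians (minimum near age 1) and
~4.4% six-year islet-autoimmunity / ~1.7% T1D cumulative incidence.

Two association modes are supported.  ``assoc_process="intake"`` puts the
hazard on the intake trajectory itself; ``assoc_process="density"`` defines
the latent process on the nutrient-density scale (units/MJ) together with a
latent energy process, writes the observed intake as density x energy, and
lets the hazard depend on both latent processes — the generating model of the
multivariate nutrient-density analysis.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .hazard import DEFAULT_CHANGEPOINTS, quadrature_grid
from .splines import SplineSpec, natural_cubic_basis
from .variables import VARIABLES, LC_N3_COMPONENTS

log = logging.getLogger(__name__)

__all__ = ["SyntheticTruth", "default_truth", "generate_cohort",
           "generate_progression_cohort", "simulate_event_time",
           "calibrate_baseline_rates", "trajectory_ranef_cov", "SCHEDULE"]

#: food-record visit ages in years (5-year visit only for a subset)
SCHEDULE = (0.25, 0.5, 1.0, 2.0, 3.0, 4.0, 5.0, 6.0)
FIVE_YEAR_VISIT_PROB = 0.13

DEFAULT_SPEC = SplineSpec((0.25, 6.0), (1.0, 2.0, 4.0))

# least-squares natural-spline coefficients through J-shaped age medians
_FAT_BETA = (32.2941, -9.0304, 27.6246, -47.4411, 21.2875)       # g/day
_ENERGY_BETA = (1.8089, 2.0862, -2.2010, 3.2337, -1.0222)        # MJ/day
_DENSITY_BETA = (15.0887, -9.7708, 18.0948, -29.4881, 11.9727)   # g/MJ

#: covariate prevalences of the study population
PREVALENCE = {
    "male": 0.531,
    "hla_high": 0.196,
    "familial": {"yes": 0.059, "no": 0.903, "missing": 0.038},
    "maternal_education": {"none": 0.10, "vocational": 0.30,
                           "secondary_vocational": 0.35, "university": 0.23,
                           "missing": 0.02},
}


def trajectory_ranef_cov(spec: SplineSpec = DEFAULT_SPEC, sd: float = 1.0,
                         corr: float = 0.6, anchor_ages=None) -> np.ndarray:
    """Random-effect covariance G inducing a stable trajectory spread.

    A covariance specified directly on the spline-coefficient scale produces
    trajectory variance that blows up near the boundary (the cubic basis
    columns are large there).  Instead, child-level deviations are specified
    at anchor ages — sd ``sd`` at every anchor, exchangeable correlation
    ``corr`` — and mapped through the inverse basis:  b = B_a^{-1} z gives
    G = B_a^{-1} Sigma_z B_a^{-T}, so x(t)'b has sd ~ ``sd`` across the
    whole follow-up.
    """
    if anchor_ages is None:
        lo, hi = spec.boundary_knots
        anchor_ages = np.concatenate([[lo], spec.internal_knots, [hi]])
    B = natural_cubic_basis(np.asarray(anchor_ages, float), spec)
    if B.shape[0] != B.shape[1]:
        raise ValueError("number of anchor ages must equal the basis size")
    m = B.shape[0]
    Sigma_z = sd ** 2 * ((1 - corr) * np.eye(m) + corr * np.ones((m, m)))
    A = np.linalg.inv(B)
    G = A @ Sigma_z @ A.T
    return 0.5 * (G + G.T)


@dataclass
class SyntheticTruth:
    """Generating parameters of a simulated cohort (kept for recovery tests).

    ``fixed_spline_coefs`` are on the model-unit scale of ``variable``
    (units/day in intake mode, units/MJ in density mode); ``assoc_coef`` is
    the log hazard ratio per one model unit of the associated process.
    """

    variable: str = "total_fat"
    spec: SplineSpec = DEFAULT_SPEC
    fixed_spline_coefs: np.ndarray = field(
        default_factory=lambda: np.array(_FAT_BETA))
    ranef_cov: np.ndarray = field(
        default_factory=lambda: trajectory_ranef_cov(DEFAULT_SPEC, sd=5.0))
    resid_sd: float = 6.0
    assoc_coef: float = 0.0
    cov_log_hr: np.ndarray = field(
        default_factory=lambda: np.array([0.30, 0.64, 0.79]))
    baseline_rates: np.ndarray = field(
        default_factory=lambda: np.array([0.00667, 0.00642, 0.00500]))
    changepoints: tuple[float, float] = DEFAULT_CHANGEPOINTS
    dropout_hazard: float = 0.0719
    seed: int = 20041996
    assoc_process: str = "intake"
    energy_spline_coefs: np.ndarray = field(
        default_factory=lambda: np.array(_ENERGY_BETA))
    energy_ranef_cov: np.ndarray = field(
        default_factory=lambda: trajectory_ranef_cov(DEFAULT_SPEC, sd=0.4))
    energy_resid_sd: float = 0.45
    energy_assoc_coef: float = 0.0
    #: T1D hazard after seroconversion (piecewise, since-seroconversion scale)
    progression_rates: np.ndarray = field(
        default_factory=lambda: np.array([0.17, 0.17, 0.17]))
    #: baseline T1D hazard of the broader repeatedly-seropositive cohort
    #: (lower than the post-IA clock; ~12.7% six-year progression)
    progression_cohort_rates: np.ndarray = field(
        default_factory=lambda: np.array([0.026, 0.026, 0.026]))
    sc_age_log_hr: float = 0.0

    def __post_init__(self):
        for name in ("fixed_spline_coefs", "cov_log_hr", "baseline_rates",
                     "energy_spline_coefs", "progression_rates",
                     "progression_cohort_rates"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), float))
        for name in ("ranef_cov", "energy_ranef_cov"):
            G = np.asarray(getattr(self, name), float)
            if not np.allclose(G, G.T):
                raise ValueError(f"{name} must be symmetric")
            if np.any(np.linalg.eigvalsh(G) < -1e-10):
                raise ValueError(f"{name} must be positive semidefinite")
            object.__setattr__(self, name, G)
        if np.any(self.baseline_rates <= 0) or np.any(self.progression_rates <= 0):
            raise ValueError("baseline rates must be positive")
        if self.assoc_process not in ("intake", "density"):
            raise ValueError("assoc_process must be 'intake' or 'density'")
        if self.variable not in VARIABLES:
            raise ValueError(f"unknown variable {self.variable!r}")


def default_truth(**overrides) -> SyntheticTruth:
    """Study-condition defaults; density mode swaps in the density-scale
    trajectory."""
    truth = SyntheticTruth(**overrides)
    if truth.assoc_process == "density" and "fixed_spline_coefs" not in overrides:
        truth = replace(truth, fixed_spline_coefs=np.array(_DENSITY_BETA),
                        ranef_cov=trajectory_ranef_cov(truth.spec, sd=1.2),
                        resid_sd=1.1)
    return truth


def simulate_event_time(cumulative_hazard, u: float, t_max: float = 6.0,
                        tol: float = 1e-8) -> float:
    """Invert H(t) = -log(u) by bisection on [0, t_max].

    Returns ``inf`` when the event falls beyond ``t_max``.  ``cumulative_hazard``
    must be nondecreasing with H(0) = 0.
    """
    if not (0.0 < u < 1.0):
        raise ValueError("u must be in (0, 1)")
    target = -np.log(u)
    grid = np.linspace(0.0, t_max, 9)
    H_grid = np.array([cumulative_hazard(t) for t in grid])
    if abs(H_grid[0]) > 1e-10 or np.any(np.diff(H_grid) < -1e-10):
        raise ValueError("cumulative hazard must be nondecreasing with H(0)=0")
    if H_grid[-1] < target:
        return float("inf")
    lo, hi = 0.0, t_max
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if cumulative_hazard(mid) < target:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def _trajectory_at(times_2d, spec, coefs):
    """m_i at a (n, q) grid of times given per-subject coefficients (n, k)."""
    n, q = times_2d.shape
    B = natural_cubic_basis(times_2d.ravel(), spec).reshape(n, q, -1)
    return np.einsum("nqk,nk->nq", B, coefs)


def _event_times(truth: SyntheticTruth, W_lin, coef_sets, t_max, u,
                 rates=None, sc_cov_lin=0.0):
    """Vectorised bisection inversion of the per-child cumulative hazard.

    ``coef_sets`` is a list of (spec, coefs (n,k), alpha) association
    processes; ``W_lin`` the covariate linear predictor.
    """
    rates = truth.baseline_rates if rates is None else np.asarray(rates, float)
    log_rates = np.log(rates)
    n = W_lin.size
    target = -np.log(u)

    def cumhaz(t_vec):
        nodes, weights, seg = quadrature_grid(
            np.maximum(t_vec, 1e-12), truth.changepoints, order=9)
        assoc = np.zeros_like(nodes)
        for spec, coefs, alpha in coef_sets:
            if alpha != 0.0:
                assoc += alpha * _trajectory_at(nodes, spec, coefs)
        integ = weights * np.exp(log_rates[seg][None, :] + assoc)
        return np.exp(W_lin + sc_cov_lin) * integ.sum(axis=1)

    lo = np.zeros(n)
    hi = np.full(n, float(t_max)) if np.ndim(t_max) == 0 else np.asarray(t_max, float)
    beyond = cumhaz(hi) < target
    for _ in range(40):
        mid = 0.5 * (lo + hi)
        below = cumhaz(mid) < target
        lo = np.where(below, mid, lo)
        hi = np.where(below, hi, mid)
    t = 0.5 * (lo + hi)
    t[beyond] = np.inf
    return t


def _draw_covariates(rng, n):
    sex = np.where(rng.random(n) < PREVALENCE["male"], "male", "female")
    hla = np.where(rng.random(n) < PREVALENCE["hla_high"], "high", "moderate")
    fam_levels = list(PREVALENCE["familial"])
    fam = rng.choice(fam_levels, size=n, p=list(PREVALENCE["familial"].values()))
    edu_levels = list(PREVALENCE["maternal_education"])
    edu = rng.choice(edu_levels, size=n,
                     p=list(PREVALENCE["maternal_education"].values()))
    bf_end = np.exp(rng.normal(np.log(0.58), 0.8, n))
    bf_end = np.clip(bf_end, 0.02, 3.0)
    return sex, hla, fam, edu, bf_end


def encode_covariates(children: pd.DataFrame, include_missing: bool = True):
    """Encode the survival covariate vector w_i: male, high HLA, familial
    diabetes yes (+ optional missing-information indicator)."""
    cols = {
        "male": (children["sex"] == "male").astype(float),
        "hla_high": (children["hla_risk"] == "high").astype(float),
        "familial_yes": (children["familial_diabetes"] == "yes").astype(float),
    }
    if include_missing:
        cols["familial_missing"] = (
            children["familial_diabetes"] == "missing").astype(float)
    return pd.DataFrame(cols, index=children.index)


def _observe_records(rng, truth, ids, coefs, energy_coefs, censor_age,
                     schedule, sc_age=None):
    """Visit retention + noisy observation; returns the records table."""
    unit = VARIABLES[truth.variable].unit
    rows = []
    n = len(ids)
    schedule = np.asarray(schedule, float)
    keep5 = rng.random(n) < FIVE_YEAR_VISIT_PROB
    n_floor = 0
    for j, age in enumerate(schedule):
        attend = censor_age >= age - 1e-9
        if age == 5.0:
            attend = attend & keep5
        idx = np.where(attend)[0]
        if idx.size == 0:
            continue
        t = np.full(idx.size, age)
        tt = t if sc_age is None else t - sc_age[idx]
        B = natural_cubic_basis(tt, truth.spec)
        latent = np.einsum("nk,nk->n", B, coefs[idx])
        energy_latent = np.einsum("nk,nk->n", B, energy_coefs[idx])
        energy = energy_latent + rng.normal(0, truth.energy_resid_sd, idx.size)
        energy = np.clip(energy, 0.15, None)
        y = latent + rng.normal(0, truth.resid_sd, idx.size)
        n_floor += int(np.sum(y < 0))
        y = np.clip(y, 0.0, None)
        if truth.assoc_process == "density":
            intake_g = y * energy * unit.grams      # y is units/MJ
        else:
            intake_g = y * unit.grams               # y is units/day
        rows.append(pd.DataFrame({
            "child_id": ids[idx], "age": age,
            "n_days": rng.choice([1, 2, 3], size=idx.size, p=[0.15, 0.30, 0.55]),
            "energy_mj": energy, truth.variable: intake_g,
        }))
    if n_floor:
        log.info("floored %d negative intake observations at 0", n_floor)
    records = pd.concat(rows, ignore_index=True)
    records = records.sort_values(["child_id", "age"]).reset_index(drop=True)
    if truth.variable == "lc_n3_pufa":
        shares = np.array([0.04, 0.03, 0.25, 0.01, 0.02, 0.07, 0.58])
        for name, s in zip(LC_N3_COMPONENTS, shares):
            records[name] = records["lc_n3_pufa"] * s
    return records


# per-variable median curves (model units/day at the schedule ages), a
# J-shaped profile scaled to each variable's overall median; long-chain n-3
# intake is instead highest in infancy (breastmilk) and low afterwards
_MEDIAN_CURVES = {
    "total_fat": [30, 28, 25, 31, 34, 36, 38, 40],
    "sfa": [12.4, 11.6, 10.4, 12.9, 14.1, 15.0, 15.8, 16.6],
    "mufa": [11.0, 10.3, 9.2, 11.4, 12.8, 13.5, 14.2, 15.0],
    "n6_pufa": [33, 31, 28, 34, 38, 40, 42, 44],
    "n3_pufa": [9.4, 8.7, 7.8, 9.7, 10.7, 11.3, 11.9, 12.5],
    "cla": [5.6, 5.2, 4.7, 5.8, 6.4, 6.8, 7.1, 7.5],
    "lc_n3_pufa": [2.8, 2.2, 0.9, 0.45, 0.42, 0.42, 0.45, 0.48],
}

# components generated as (clipped) fractions of their parent class so that
# each sub-component never exceeds its parent
_COMPONENT_FRACTIONS = {
    "myristic_acid": ("sfa", 0.123),        # 100 mg units vs g units: x10
    "palmitic_acid": ("sfa", 0.52),
    "linoleic_acid": ("n6_pufa", 0.95),
    "arachidonic_acid": ("n6_pufa", 0.0103),
    "alpha_linolenic_acid": ("n3_pufa", 0.885),
}


def _add_secondary_variables(records: pd.DataFrame, rng,
                             focal: str) -> pd.DataFrame:
    """Intake columns (g/day) for the non-focal fat variables.

    Top-level classes follow their median-by-age curve with a child-level
    multiplier and record noise; named fatty acids are fractions of their
    parent class.  Not a spline process — these columns support the
    full-grid pipeline and reporting, while the focal variable carries the
    exact generating model.
    """
    schedule = np.asarray(SCHEDULE)
    age_idx = np.searchsorted(schedule, records["age"].to_numpy(float))
    kids = records["child_id"].to_numpy()
    uniq = pd.unique(kids)
    pos = pd.Series(np.arange(len(uniq)), index=uniq)
    child_ix = pos[kids].to_numpy()
    out = records.copy()
    for name, curve in _MEDIAN_CURVES.items():
        if name == focal:
            continue
        unit_g = VARIABLES[name].unit.grams
        mult = np.exp(rng.normal(0.0, 0.20, len(uniq)))[child_ix]
        base = np.asarray(curve, float)[age_idx]
        noise = rng.normal(0.0, 0.12 * base)
        vals = np.clip(base * mult + noise, 0.0, None)
        out[name] = vals * unit_g
    for name, (parent, frac) in _COMPONENT_FRACTIONS.items():
        if name == focal or parent not in out.columns:
            continue
        f = np.clip(frac * np.exp(rng.normal(0.0, 0.08, len(out))), None, 0.99)
        out[name] = out[parent] * f
    if "lc_n3_pufa" in out.columns and focal != "lc_n3_pufa":
        shares = np.array([0.04, 0.03, 0.25, 0.01, 0.02, 0.07, 0.58])
        for comp, s in zip(LC_N3_COMPONENTS, shares):
            out[comp] = out["lc_n3_pufa"] * s
    return out


def generate_cohort(truth: SyntheticTruth, size: int, seed: int | None = None,
                    schedule=SCHEDULE, all_variables: bool = False):
    """Simulate a cohort; returns ``(children, records)`` DataFrames.

    Children columns: child_id, sex, hla_risk, familial_diabetes,
    maternal_education, breastfed_at_3mo, breastfeeding_end_age, ia_age,
    ia_status, t1d_age, t1d_status, censor_age.
    """
    if size < 1:
        raise ValueError("size must be >= 1")
    schedule = np.asarray(schedule, float)
    if schedule.size == 0 or np.any(np.diff(schedule) <= 0) or schedule[0] <= 0:
        raise ValueError("schedule must be strictly increasing within (0, 6]")
    rng = np.random.default_rng(truth.seed if seed is None else seed)
    ids = np.array([f"C{i:05d}" for i in range(size)])
    sex, hla, fam, edu, bf_end = _draw_covariates(rng, size)

    k = len(truth.fixed_spline_coefs)
    b = rng.multivariate_normal(np.zeros(k), truth.ranef_cov, size=size,
                                method="eigh")
    coefs = truth.fixed_spline_coefs + b
    be = rng.multivariate_normal(np.zeros(k), truth.energy_ranef_cov,
                                 size=size, method="eigh")
    energy_coefs = truth.energy_spline_coefs + be

    W = np.column_stack([(sex == "male"), (hla == "high"), (fam == "yes")]
                        ).astype(float)
    W_lin = W @ truth.cov_log_hr

    proc = [(truth.spec, coefs, truth.assoc_coef)]
    if truth.assoc_process == "density":
        proc.append((truth.spec, energy_coefs, truth.energy_assoc_coef))
    u_ia = rng.random(size)
    t_ia = _event_times(truth, W_lin, proc, 6.0, u_ia)

    dropout = rng.exponential(1.0 / truth.dropout_hazard, size)
    censor = np.minimum(dropout, 6.0)
    ia_status = (t_ia <= censor).astype(int)
    ia_age = np.where(ia_status == 1, t_ia, np.nan)

    # T1D clock restarts at seroconversion (piecewise-exponential, no assoc.)
    u_t1d = rng.random(size)
    t1d_age = np.full(size, np.nan)
    t1d_status = np.zeros(size, dtype=int)
    has_ia = ia_status == 1
    if has_ia.any():
        horizon = 6.0 - ia_age[has_ia]
        prog = _invert_piecewise(truth.progression_rates, truth.changepoints,
                                 u_t1d[has_ia])
        t1d = ia_age[has_ia] + prog
        ok = (prog <= horizon) & (t1d <= censor[has_ia])
        full_t1d = np.where(ok, t1d, np.nan)
        t1d_age[has_ia] = full_t1d
        t1d_status[has_ia] = ok.astype(int)

    children = pd.DataFrame({
        "child_id": ids, "sex": sex, "hla_risk": hla, "familial_diabetes": fam,
        "maternal_education": edu,
        "breastfed_at_3mo": bf_end > 0.25,
        "breastfeeding_end_age": bf_end,
        "ia_age": ia_age, "ia_status": ia_status,
        "t1d_age": t1d_age, "t1d_status": t1d_status,
        "censor_age": censor,
    })
    records = _observe_records(rng, truth, ids, coefs, energy_coefs, censor,
                               schedule)
    if all_variables:
        records = _add_secondary_variables(records, rng, truth.variable)
    return children, records


def _invert_piecewise(rates, changepoints, u):
    """Closed-form quantile of the piecewise-exponential distribution
    (last segment extends to infinity)."""
    rates = np.asarray(rates, float)
    starts = np.concatenate([[0.0], np.asarray(changepoints, float)])
    H_start = np.concatenate([[0.0], np.cumsum(rates[:-1] * np.diff(starts))])
    target = -np.log(np.atleast_1d(np.asarray(u, float)))
    seg = np.clip(np.searchsorted(H_start, target, side="right") - 1,
                  0, len(rates) - 1)
    return starts[seg] + (target - H_start[seg]) / rates[seg]


def generate_progression_cohort(truth: SyntheticTruth, size: int,
                                seed: int | None = None, schedule=SCHEDULE):
    """Simulate seroconverted children followed from first seroconversion.

    The latent trajectory is defined on the since-seroconversion time scale
    (records observed at the regular visit ages, so pre-seroconversion records
    exist for interpolation); the T1D hazard runs on the same scale with
    change points 1.99 / 3.99 and an age-at-seroconversion covariate.
    """
    if size < 1:
        raise ValueError("size must be >= 1")
    rng = np.random.default_rng(truth.seed if seed is None else seed)
    ids = np.array([f"P{i:05d}" for i in range(size)])
    sex, hla, fam, edu, bf_end = _draw_covariates(rng, size)
    # median 1.9 y, IQR 1.2-3.5 on the log scale
    sc_age = np.exp(rng.normal(np.log(1.9), 0.79, size))
    sc_age = np.clip(sc_age, 0.3, 5.5)

    k = len(truth.fixed_spline_coefs)
    coefs = truth.fixed_spline_coefs + rng.multivariate_normal(
        np.zeros(k), truth.ranef_cov, size=size, method="eigh")
    energy_coefs = truth.energy_spline_coefs + rng.multivariate_normal(
        np.zeros(k), truth.energy_ranef_cov, size=size, method="eigh")

    W = np.column_stack([(sex == "male"), (hla == "high"), (fam == "yes")]
                        ).astype(float)
    W_lin = W @ truth.cov_log_hr + truth.sc_age_log_hr * sc_age

    proc = [(truth.spec, coefs, truth.assoc_coef)]
    if truth.assoc_process == "density":
        proc.append((truth.spec, energy_coefs, truth.energy_assoc_coef))
    horizon = 6.0 - sc_age
    u = rng.random(size)
    t_prog = _event_times(truth, W_lin, proc, horizon, u,
                          rates=truth.progression_cohort_rates)
    status = np.isfinite(t_prog) & (t_prog <= horizon)
    t1d_age = np.where(status, sc_age + t_prog, np.nan)
    censor = np.full(size, 6.0)

    children = pd.DataFrame({
        "child_id": ids, "sex": sex, "hla_risk": hla, "familial_diabetes": fam,
        "maternal_education": edu,
        "breastfed_at_3mo": bf_end > 0.25, "breastfeeding_end_age": bf_end,
        "sc_age": sc_age,
        "ia_age": sc_age, "ia_status": 1,
        "t1d_age": t1d_age, "t1d_status": status.astype(int),
        "censor_age": censor,
    })
    records = _observe_records(rng, truth, ids, coefs, energy_coefs, censor,
                               schedule, sc_age=sc_age)
    return children, records


def calibrate_baseline_rates(truth: SyntheticTruth, target_incidence: float,
                             which: str = "ia", n_mc: int = 3000,
                             seed: int = 1234) -> np.ndarray:
    """Scale the baseline rates so the expected observed cumulative incidence
    (events before dropout/administrative censoring) matches
    ``target_incidence``.  ``which`` selects the islet-autoimmunity clock of
    the full cohort or the T1D clock of the progression cohort.  Monte-Carlo
    with common random numbers and a root-find on the log rate multiplier."""
    from scipy.optimize import brentq

    rng = np.random.default_rng(seed)
    sex, hla, fam, _, _ = _draw_covariates(rng, n_mc)
    k = len(truth.fixed_spline_coefs)
    coefs = truth.fixed_spline_coefs + rng.multivariate_normal(
        np.zeros(k), truth.ranef_cov, size=n_mc, method="eigh")
    energy_coefs = truth.energy_spline_coefs + rng.multivariate_normal(
        np.zeros(k), truth.energy_ranef_cov, size=n_mc, method="eigh")
    W = np.column_stack([(sex == "male"), (hla == "high"), (fam == "yes")]
                        ).astype(float)
    W_lin = W @ truth.cov_log_hr
    proc = [(truth.spec, coefs, truth.assoc_coef)]
    if truth.assoc_process == "density":
        proc.append((truth.spec, energy_coefs, truth.energy_assoc_coef))
    u = rng.random(n_mc)
    if which == "ia":
        rates = truth.baseline_rates
        horizon = np.full(n_mc, 6.0)
        censor = np.minimum(rng.exponential(1.0 / truth.dropout_hazard, n_mc), 6.0)
        sc_lin = 0.0
    elif which == "progression":
        rates = truth.progression_cohort_rates
        sc_age = np.clip(np.exp(rng.normal(np.log(1.9), 0.79, n_mc)), 0.3, 5.5)
        horizon = 6.0 - sc_age
        censor = horizon
        sc_lin = truth.sc_age_log_hr * sc_age
    else:
        raise ValueError("which must be 'ia' or 'progression'")

    def observed_incidence(log_c):
        t = _event_times(truth, W_lin + log_c, proc, horizon, u, rates=rates,
                         sc_cov_lin=sc_lin)
        return float(np.mean(t <= censor)) - target_incidence

    log_c = brentq(observed_incidence, -10.0, 10.0, xtol=1e-4)
    return rates * np.exp(log_c)
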