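# Methods

`fajoint` implements a joint longitudinal–survival analysis of childhood
dietary fatty-acid intake and time to islet autoimmunity (IA) or type 1
diabetes (T1D), together with a synthetic-cohort generator that emulates a
prospective birth-cohort dietary follow-up, so that every stage of the
analysis can be validated by parameter recovery without access to real data.

## The joint model

For child *i* with covariates *w<sub>i</sub>* (male sex, high-risk HLA
genotype, familial diabetes; plus age at seroconversion in the progression
analysis), the longitudinal submodel for intake of one fat variable is a
natural cubic spline linear mixed model

  y<sub>ij</sub> = x(t<sub>ij</sub>)′(β + b<sub>i</sub>) + ε<sub>ij</sub>,
  b<sub>i</sub> ~ MVN(0, G), ε<sub>ij</sub> ~ N(0, σ²),

where x(t) is the natural cubic spline basis with two boundary knots and
three internal knots, so each child carries subject-specific spline
coefficients. The survival submodel has Cox structure with a parametric
piecewise-constant baseline hazard (change points at 1.99 and 3.99 years of
follow-up) and a *current-value association*:

  h<sub>i</sub>(t) = h₀(t) exp( γ′w<sub>i</sub> + α m<sub>i</sub>(t) ),
  m<sub>i</sub>(t) = x(t)′(β + b<sub>i</sub>).

exp(α) is the hazard ratio per one model unit of intake (1 g, 100 mg or
10 mg per day; per MJ once energy-adjusted) at the same time point.
Energy adjustment follows the multivariate nutrient-density method: the
exposure becomes intake/energy (units/MJ) and total energy enters as a
second longitudinal spline process sharing the knots, with its own
association coefficient, so an energy HR per MJ is reported alongside the
density HR (a simpler mode with mean energy as a baseline covariate is
available in the config).

### Knot selection

Internal knots are selected from the distinct observed-age grid: all triples
with at least two distinct ages strictly below the first knot and strictly
above the last, and at least one year between consecutive knots, are fitted
and the minimal-BIC model is kept (ties toward the lexicographically
earliest triple). On the design's visit grid {0.25, 0.5, 1, 2, 3, 4, 5, 6}
exactly four triples are feasible: {1,2,3}, {1,2,4}, {1,3,4}, {2,3,4}.
BIC uses the number of longitudinal observations as sample size and counts
dim(β) + free elements of G + 1 parameters.

### Longitudinal fitting

The ML fit is computed by a vectorised EM algorithm over padded per-subject
arrays (each sweep provably increases the marginal likelihood; relative
tolerance 10⁻⁶ on the log-likelihood, max 2000 sweeps). G is unstructured
("full") by default, with a diagonal option for small samples. statsmodels'
MixedLM is retained as an independent engine and cross-checked in the test
suite; the EM route is the default because it reaches an equal or better
likelihood in about a fifth of the time on the selection problem. The
log-likelihood reported on a fit is always recomputed by direct per-subject
multivariate-normal evaluation at the estimates.

### Bayesian estimation

Parameters are sampled by adaptive random-walk Metropolis (Haario-style:
proposal covariance tracks the chain's empirical covariance during burn-in
only, so post-burn-in draws target the exact posterior). Three chains with
dispersed starts; convergence is the Gelman–Rubin potential scale reduction
factor with the 1.1 threshold, computed per parameter; summaries refuse to
run on unconverged chains unless overridden, in which case the summary
carries `converged=False`.

Priors are weakly informative and centred on separate submodel fits: γ and
the log baseline rates at the piecewise-exponential ML estimates (obtained
via the Poisson-regression equivalence) with 10× their standard errors
(clipped to [0.05, 2] before scaling to survive zero-event segments);
α ~ N(0, 10²) per model unit; in the full sampler β ~ N(β̂, 10·SE),
log σ ~ N(log σ̂, 1), log G-diagonal ~ N(fit, 2²). All widths are
config-overridable.

Two samplers are provided.

* **Marginal (default).** The longitudinal parameters are fixed at their ML
  estimates and the subject-specific coefficients are integrated out of the
  survival likelihood by a Laplace approximation around their longitudinal
  posterior N(b̂<sub>i</sub>, V<sub>i</sub>). Because the survival exponent
  is linear in b, the inner objective is strictly concave; a damped Newton
  iteration (step-halving line search, exponent clamp) finds the mode from
  b̂<sub>i</sub> in 2–3 steps to machine accuracy. Only (γ, log h₀, α)
  are sampled — 7–8 dimensions — which makes large simulation studies
  affordable. Cost: uncertainty in (β, G, σ²) is ignored; with hundreds of
  children and a handful of spline coefficients this is a second-order
  effect (the recovery studies below quantify it).
* **Full.** All parameters are sampled. (β), (log σ, log diag G) and
  (γ, log h₀, α) are updated as Metropolis blocks against the *collapsed*
  posterior — the Gaussian marginal likelihood for the longitudinal part
  and the same Laplace marginal for the survival part — and the random
  effects are then refreshed by an independence Metropolis step proposing
  from N(b̂<sub>i</sub>, V<sub>i</sub>), whose acceptance ratio reduces
  exactly to the per-subject survival-likelihood difference. Collapsing is
  what makes this sampler mix: a naive per-subject random-walk on the
  {b<sub>i</sub>} leaves α essentially frozen. Only a diagonal G is sampled
  in this mode.

In both samplers the association exponent is centred, α·(m(t) − c) with c
the cohort-average trajectory level: without centring, α and the log
baseline rates lie on a near-degenerate ridge of slope ≈ mean intake and no
random-walk sampler traverses it. Hazard ratios per unit are unchanged; the
sampled log-rates refer to the baseline hazard at the average intake level.

The cumulative hazard under the association has no closed form; it is
integrated by fixed-order Gauss–Legendre quadrature within each baseline
segment (15 nodes per segment by default; order 5 is used in the simulation
studies, where it agrees with order 15 to ~10⁻⁴ log-likelihood units).
Ties need no special treatment in this fully parametric continuous-time
likelihood.

### Progression analysis

Among seroconverted children the time scale is time since first
seroconversion (censored at age 6), with the same change points on that
scale and an additional centred age-at-seroconversion covariate. Records at
or after seroconversion enter the longitudinal submodel; because nobody is
measured exactly at seroconversion, a pseudo-record at time zero is linearly
interpolated between the nearest record before and after seroconversion
(each nutrient and energy independently; no extrapolation when no earlier
record exists). The pseudo-record enters the LME with the same residual
variance as a real record. This is deliberately approximate — its error is
smaller than σ and correlated with the bracketing record — and with noisy
exposure processes (residual sd comparable to the between-child sd) it
measurably attenuates α; with dispersion matched to the printed intake
spread the attenuation is negligible (see the recovery study).

## Supporting analyses

* **Early-intake Cox screen.** Mean energy-adjusted intake over the 3- and
  6-month records as a time-independent covariate in a Cox model (statsmodels
  PHReg; Breslow ties by default, Efron by option), adjusted for sex, HLA and
  familial diabetes; children with neither early record are excluded.
  Maternal education is accepted but excluded from defaults.
* **Breastfeeding interaction.** The same model plus breastfed-at-3-months
  and its product with the (centred) early intake; Wald test of the product.
* **Multiple testing.** Benjamini–Hochberg step-up at q = 0.05 over the
  joint-model family (12 fat variables × 2 adjustments × 3 outcomes = 72
  tests). Joint-model "p-values" are twice the smaller posterior tail
  probability of α, floored at 2/draws — a documented convention, switchable.
* **Sensitivity exclusion.** Food records within 18 months before a T1D
  diagnosis can be dropped (T1D outcome only) to probe reverse causality.
* **Nutrient processing.** For breastfed infants total energy is imputed
  from an age-band × body-weight requirement table (per-kg values shipped as
  an editable CSV; default median weight-for-age used when weight is
  missing); breastmilk energy is the floored shortfall between requirement
  and recorded food energy, converted to grams at 2.8 kJ/g (configurable),
  with an optional per-100 g breastmilk fatty-acid composition vector added
  to intakes. Long-chain n-3 PUFA is the sum of the seven constituent
  fatty acids (20:3n-3, 20:4n-3, 20:5n-3, 21:5n-3, 22:4n-3, 22:5n-3,
  22:6n-3). Three-day records are assumed pre-averaged to daily means.

## The synthetic cohort

The generator emulates the study conditions: visit schedule 0.25, 0.5, 1,
2, 3, 4, (5), 6 years (the 5-year visit attended by ~13% of children, the
share implied by the printed record-day counts); dropout as an independent
exponential process at rate 0.0719/y, all-or-nothing after the dropout
time, giving ~6.9/13.4/35% cumulative dropout at 1/2/6 y (the closest a
single-rate mechanism comes to the reported 6/14/35%); covariate
prevalences 53.1% male, 19.6% high HLA, familial diabetes
5.9/90.3/3.8% yes/no/missing; record-day mix averaging ~14.3 days per
child; J-shaped intake-by-age median curves with the minimum near age 1
(long-chain n-3 instead peaks in infancy, reflecting breastmilk); and
events from the exact current-value proportional hazard, inverted by
bisection of the quadrature cumulative hazard to 10⁻⁸. T1D follows a
second piecewise-exponential clock restarted at seroconversion. Baseline
rates are calibrated by a common-random-number Monte-Carlo root-find so the
observed cumulative incidence matches ~4.4% (IA), ~1.7% (T1D overall) and
~12.7% (progression cohort).

Random-effect covariances are specified on the trajectory scale
(`trajectory_ranef_cov`): child deviations with a chosen sd and
exchangeable correlation at anchor ages, mapped through the inverse basis.
Specifying G directly on the coefficient scale silently produces trajectory
variance that explodes near the right boundary knot.

Design choices and non-goals: covariates do not influence diet; the 12 fat
variables other than the focal one are generated as median-curve ×
child-level lognormal multiplier with components tied to their parent class
(so sub-component ≤ parent holds), i.e. realistic in level and shape but
not cross-correlated as real diets are; no within-child serial correlation
beyond the random effects; intakes are floored at zero after noise; no
food-level structure. Passing recovery tests on these cohorts demonstrates
that the estimation machinery recovers the generating process under the
study's design, sample sizes and event rates — not that the model is
correctly specified for real dietary data.

## Validation by parameter recovery

Three protocols (`fajoint.validate`), each 20 replicates of n = 300 with
shortened chains (3 × 1500, burn-in 900, Laplace-marginal sampler):

* **null** — MUFA-like intake process (between-child sd 2 g/day, residual
  2.5), α = 0;
* **hr063** — same process, HR 0.63 per g/day;
* **hr052** — progression cohort, SFA-like density process (between-child
  sd 1.2 g/MJ, residual 0.7, matched to the printed intake IQR) with an
  energy process (HR 1.35 per MJ), density HR 0.52 per g/MJ.

The check is that the 95% credible interval covers the generating log HR in
at least 17 of 20 replicates, and that any parameter with Gelman–Rubin
statistic ≥ 1.1 is flagged on the fit. At n = 3000 the point estimates are
unbiased (e.g. −0.649 recovered vs −0.654 truth for hr052). The full
protocol takes roughly 10–12 minutes on one CPU.

Null calibration of the interaction screen (KS test of Wald p-values over
200 simulated cohorts) and the interaction power check use elevated
baseline rates (~20% six-year incidence) so the Wald asymptotics are
informative at n = 500–2000; these are machinery checks, not study
emulation.

## Numerical details and limitations

* Quadrature: Gauss–Legendre per baseline segment; error decreases
  monotonically with order (tested); order < 3 rejected.
* Event-time inversion: bisection to 10⁻⁸ with a +∞ sentinel past the
  6-year horizon; nondecreasing cumulative hazard asserted on a coarse grid.
* Degenerate inputs: non-PSD G, nonpositive rates or energies, negative
  intakes, empty schedules and out-of-support parameters raise or return
  −∞ as appropriate; Cox covariates without variation get coefficient 0
  with infinite variance and a warning; separation raises naming the
  covariate.
* Zero within-chain variance yields an undefined (NaN) Gelman–Rubin value
  with a warning.
* The marginal sampler fixes longitudinal parameters at their ML estimates;
  its intervals ignore that source of uncertainty. The full sampler removes
  this at ~5× the cost but supports a single longitudinal process and a
  diagonal G.
* The progression pseudo-record convention is approximate (see above); with
  very noisy exposures it attenuates the association.
* Missing familial-diabetes information is kept as its own indicator level
  by default (complete-case available).
* Rounding of reported percentages is half-up, matching printed one-decimal
  cohort tables.
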