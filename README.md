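# fajoint

Joint longitudinal–survival modelling of childhood dietary fatty-acid
intake and the risk of islet autoimmunity (IA) and type 1 diabetes (T1D),
for biostatisticians and nutritional epidemiologists working with
birth-cohort dietary follow-up data.

A child's intake of a fat variable is modelled as a natural cubic spline
mixed model with subject-specific spline coefficients,

    y_ij = x(t_ij)'(β + b_i) + ε_ij,     b_i ~ MVN(0, G),

and linked to the time until IA or T1D through a proportional hazard with a
piecewise-constant baseline (change points 1.99 and 3.99 y) and a
current-value association,

    h_i(t) = h0(t) · exp( γ'w_i + α · m_i(t) ),   m_i(t) = x(t)'(β + b_i),

so exp(α) is the hazard ratio per one unit of intake (1 g, 100 mg or
10 mg/day — per MJ once energy-adjusted by the multivariate nutrient-density
method, in which total energy enters as a second longitudinal process).
Internal knots are chosen by BIC over all feasible triples on the visit
grid; estimation is Bayesian (adaptive-Metropolis MCMC, Gelman–Rubin
convergence checks, posterior-mean HRs with 95% credible intervals), with a
fast Laplace-marginalised sampler as the default. The package also covers
the surrounding analyses: breastfed-infant energy imputation and breastmilk
quantity, nutrient-density adjustment, the seroconversion-anchored
progression analysis with its interpolated intake at seroconversion, the
early-intake Cox screen with a breastfeeding-interaction test,
Benjamini–Hochberg FDR over the model family, and a synthetic-cohort
generator that emulates the study design (visit schedule, dropout,
covariate mix, J-shaped intake curves, ~4.4%/1.7% six-year IA/T1D
incidence) so everything is testable by parameter recovery.
See `docs/methods.md` for the model details and design choices.

## Worked example

```python
from fajoint import JointConfig, fit_joint
from fajoint.simulate import default_truth, generate_cohort

truth = default_truth()                       # study-like conditions
children, records = generate_cohort(truth, 2000, seed=1, all_variables=True)
print(len(children), int(children.ia_status.sum()))
# 2000 91

cfg = JointConfig(seed=1, ranef="diagonal", quad_order=5)   # 3 x 4000 draws
fit = fit_joint(children, records, "total_fat", outcome="ia", config=cfg)
print(fit.knot_table[["knots", "bic"]])
#              knots           bic
# 0  (1.0, 2.0, 3.0)  82188.516884
# 1  (1.0, 2.0, 4.0)  82177.080132
# 2  (1.0, 3.0, 4.0)  82257.366917
# 3  (2.0, 3.0, 4.0)  82508.483106
print(f"HR {fit.hr:.2f} ({fit.hr_ci[0]:.2f}, {fit.hr_ci[1]:.2f}) "
      f"p={fit.p_value:.3f} converged={fit.converged}")
# HR 0.96 (0.90, 1.01) p=0.109 converged=True
```

The cohort shows 91 islet-autoimmunity events among 2000 children (4.6%,
matching the ~4.4% design incidence). The BIC table lists the four feasible
knot triples on the visit grid with {1, 2, 4} selected, and since the
generator's default association is null, the credible interval for the
hazard ratio per g/day of total fat covers 1.00 (all Gelman–Rubin
statistics ≤ 1.02). The fit takes a few minutes at the default chain
length; `JointConfig(n_iter=1500, burn_in=900)` gives a quick look. This
summary is one row of the results table the pipeline assembles for every
variable × adjustment × outcome combination before FDR correction.

The `analysis/` scripts run the full narrative (simulate → summarise →
joint models → progression → early-intake screen → recovery study), each
writing its tables under `results/`. A `fajoint` command-line interface
wraps the same stages (`fajoint simulate`, `fajoint fit --variable mufa
--outcome ia`, `fajoint run --config config.yaml`, ...).

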