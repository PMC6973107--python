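# Methods

This note records the models implemented in `smach`, the assumptions behind
them, the defaults and why they were chosen, and what the synthetic-data
generators do and do not emulate.

## Dosimetry chain

Urinary metabolite concentrations (µg/L) are converted to a molar daily
intake of the parent compound by

    DI [mol/kg bw/day] = UE [mol/g crt] × CE [g crt/kg bw/day] / F_UE,

where UE sums `conc/MW` over the parent's measured metabolites (one shared
excretion fraction per parent — DEHP uses four metabolites, DINP three, DBP
and BBzP one each) and divides by urinary creatinine in g/L (creatinine
mmol/L × 113.12 / 1000; the molar mass is fixed, not configurable). Defaults:
CE = 0.023 g/kg/day for pregnant women; excretion fractions and molecular
weights ship in `data/constants.yaml`.

Intake maps to steady-state plasma concentration through a one-compartment
model with complete oral bioavailability:

    Cp = DI × t½ / (0.693 × V_d),    t½ = 0.4 d,  V_d = 0.2 L/kg bw.

The conventional rounded constant 0.693 (not `ln 2` at machine precision) is
used so the two directions are exact algebraic inverses; the round trip is
the identity to ~1e-15 relative error.

Reference-mixture proportions are the per-parent geometric-mean serum levels
normalized to sum to one. Proportions are carried at full precision;
two-decimal values are for display only. Zero intakes are excluded from a
geometric mean (with a warning counting exclusions). Values below a limit of
detection can be substituted by LOD/√2 (default), LOD/2, LOD, or dropped —
the choice is explicit because it is a genuine analysis decision, not a
neutral preprocessing step.

BPA and triclosan have excretion factors in the constants file and the
dosimetry operations accept them, but the pipeline excludes phenols from the
reference mixture by default (`excluded_parents`): the mixture is defined on
the phthalate diesters.

## Weighted quantile sum regression

Exposures are scored into empirical quantile bins (quartiles by default);
ties at a bin edge fall in the lower bin; a constant component scores zero
with a warning. The index model is estimated under `w ≥ 0`, `Σw = 1` and a
fixed sign for the index coefficient. Numerically, weights are
reparameterized through a softmax and the coefficient through
`β₁ = sign · exp(θ)`, giving a smooth unconstrained least-squares problem
solved by L-BFGS with analytic gradients; replicates that fail to converge
are dropped (counted in the result) and an all-failure run raises.

Weight estimation uses a bootstrap ensemble (default 100 replicates) on a
training split (default 40% of subjects); final weights are the average of
replicate weights, weighted by each replicate's |t| statistic for the index
coefficient (a plain mean is available). Inference on the final index —
estimate, SE, two-sided p — comes from an ordinary linear model of the
outcome on the fixed index plus covariates in the held-out evaluation split,
so the weight search does not contaminate the test.

When the training split cannot support the parameter count (fewer than
5×(components + covariates + 2) subjects), the fit falls back to
train = evaluate on the full sample and flags the result. This mirrors what
a small cohort forces in practice, but the resulting p-value inherits the
weight-selection optimism and should be treated as descriptive: in null
simulations the full-data mode rejects at ≈ 0.24 at nominal 0.05, while the
split-sample mode is calibrated (measured 0.04 over 500 replicates).

Bad actors are the components with weight strictly above 1/c. With the
strict rule a weight exactly at the threshold is not selected.

Covariates enter linearly and unpenalized; only complete cases are used.

## Dose–response and benchmark dose

The animal response (anogenital distance / body weight) is modelled on
`x = log₁₀(dose + 1)` — so the control maps to x = 0 — by a quadratic with
a random litter intercept, estimated by maximum likelihood (REML optional).
Litters are the unit of independence; pups within a litter are exchangeable.

The benchmark response is a relative decline from the *model-predicted*
control mean β₀ (not the observed control group mean; a config switch is not
offered because the root equation is defined in terms of β₀). The BMD solves
`β₁x + β₂x² + bmr·β₀ = 0`; the smallest positive real root is taken,
and absent a positive real root the code raises ("benchmark response not
reached") rather than extrapolating. Its SE follows from the delta method
via implicit differentiation (gradient `−(bmr, x, x²)/(β₁ + 2β₂x)`),
cross-checked against finite differences in the tests; a near-zero slope of
the defining equation at the root flags the SE as unstable. The BMDL is the
one-sided bound `BMD − t(0.95, df)·SE`. The similarity radius is
`R = ED(8%) − BMD(5%)` on the same log scale.

**Fixed-effect covariance.** Dose varies only between litters, so the dose
coefficients are whole-litter effects. The plug-in ML covariance, which
conditions on the estimated variance components, is anti-conservative with
few litters: in simulation at 4–6 dams per dose its 90% coefficient
intervals cover at ≈ 77%. The default therefore rebuilds the covariance at
the litter level — litter means weighted by the inverse of their model
variance `s²_litter + s²_resid/n_pups`, scaled by the observed
between-litter dispersion, with between-litter degrees of freedom
(litters − 3). This restores 88–91% coverage of the 90% delta-method BMD
interval in the same simulations. `cov_method="plugin"` retains the raw ML
covariance with df = N − 3 for comparison.

Dunnett screening uses the same litter-level construction: each dose group
mean is a variance-weighted mean of litter means, contrasts share the
control mean (product correlation), and family-wise adjusted p-values are
`P(max|T| ≥ |t|)` under the joint multivariate-t null, evaluated by a
seeded Monte Carlo draw (closed-form quadrature holds only for
product-correlation designs, which unbalanced litter layouts do not
guarantee). Measured family-wise error under the null: 0.038–0.052 over 500
replicates of the 4-group design. Comparisons are two-sided.

A degenerate likelihood (an exact, noise-free polynomial fit) falls back to
ordinary least squares on the same design; with zero litter variance the
mixed fit and OLS agree in the fixed effects.

## Similarity, SMRI, hazard index

Distance, upper limit and the strict decision rule `UL < R` follow the
formulas in the README. Units: subject exposures `E_j` are steady-state
serum concentrations (mol/L) on the same scale as the 1X anchor; the
reference dose is `T_r = (10^BMD − 1) × anchor_total` mol/L, with
`SE(T_r) = ln10 · 10^BMD · SE(BMD) · anchor_total` by the delta method, and
the radius converted to the same concentration scale. The conversion chain
is logged in the run provenance. Degrees of freedom are inherited from the
dose–response fit.

The SMRI is implemented verbatim: `SMRI = Σⱼ Eⱼ/(a_rj·T_r)`. Note that a
subject exactly at the reference proportions with total exposure `T_r`
scores the number of components (each quotient is 1), not 1; an optional
`normalize` flag dividing by the component count is provided as an
extension and is off by default. Strict inequalities are used throughout
(`UL < R`, `SMRI > 1`, `conc > BE`).

Subjects with all-zero exposures have undefined mixture proportions; they
are excluded from similarity scoring and reported separately
(`n_unscored`). The hazard index sums concentration/guideline quotients on
each guideline's metabolite basis (the DEHP guideline is on the sum of four
metabolites); guideline values ship in `data/be_values.yaml`. The monoester
vs diester basis for proportions is a config concern: the default constants
define the diester basis, and an alternate constants file can redefine the
molar basis without code changes.

## Synthetic data

The cohort generator draws correlated lognormal exposures (exchangeable
log-scale correlation 0.3 by default — a typical same-class biomonitoring
correlation; configurable), lognormal creatinine (median 9.8 mmol/L, log-SD
0.45 chosen to match a reported interquartile range of 6), and Gaussian
covariates anchored to reported cohort summaries (age 21 ± 1.6 months,
weight percentile 56 ± 27, gestational week 10 ± 2.3). The outcome is
generated from the *quantiled* exposures — `AGD = μ₀ + β₁Σw*ⱼqⱼ +
covariate effects + noise` — so the WQS estimand is exactly the planted
truth; a raw-concentration variant exists to probe robustness to that
choice. μ₀ and the residual SD are solved so the marginal outcome matches
its anchors (mean 41.4 mm, SD 6.1 mm). Default planted weights concentrate
on the DINP and BBzP metabolites with β₁ = −1.6, echoing the reported
association pattern.

The litter generator draws `response = β₀ + β₁x + β₂x² + litter + ε` at
doses (0, 0.5, 10, 100)×, default 4 dams per dose and 5 pups per dam,
litter SD 0.03 and residual SD 0.05, with per-dose overrides to mirror the
unbalanced group sizes and SDs of the real study. The default truth
β = (1.0, −0.17, 0.07) implies BMD(5%) = 0.342 and a maximum decline of
≈ 10.3%, so the 8%-decline effective dose exists in truth but is not
estimable in roughly one simulated study in ten (the fitted curve never
reaches 8%); `effective_dose` then raises, and the pipeline aborts step 3
with that message. The end-to-end demonstration in
`scripts/acceptance.py` redraws the animal study (bounded at ten attempts,
seeds derived from `--seed`) and reports the attempt count.

What the generators do *not* emulate — and hence what passing tests do not
establish about real data: limit-of-detection censoring beyond a simple
cut, non-exchangeable exposure correlation, measurement error in creatinine
or the outcome, confounder–exposure correlation (covariates are drawn
independently of exposures, so covariate adjustment is exercised but not
stressed), and between-subject heterogeneity in mixture proportions large
enough to make similarity fail: because every synthetic subject is drawn
from one exposure distribution centred on the reference, essentially all
synthetic subjects are sufficiently similar, unlike a real population.

## Problem sizes and determinism

Simulation-based checks use: 20 cohorts of n = 500 for WQS recovery, 500
cohorts of n = 500 for the null size, 200 litter studies (4–6 dams per
dose) for BMD recovery and coverage, and 500 null replicates for the
Dunnett family-wise error — sizes at which the Monte-Carlo error of each
rate is a few percent. All randomness flows through seeded NumPy
generators; identical seeds give identical tables, reports and artifacts.

## Known limitations

- The small-sample (no-split) WQS mode is anti-conservative by
  construction; its p-values are descriptive.
- The delta-method BMD interval relies on a local linearization; with
  nearly coincident roots the SE is flagged unstable rather than corrected
  (no profile-likelihood interval is implemented).
- The Dunnett adjustment uses Monte-Carlo tail probabilities (seeded, n
  configurable), so adjusted p-values carry ~1/√n_mc noise.
- The similarity rule treats the distance and its upper limit as the
  complete data-poor decision; no per-subject dose–response is estimated.
- One-compartment, single-half-life toxicokinetics for all parents; no
  physiologically based modelling.
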