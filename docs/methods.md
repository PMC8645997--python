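# Methods

## Structural model and solver

Drug disposition is a linear two-compartment model with zero-order infusion
input. Micro rate constants are k10 = CL/V, k12 = Q/V, k21 = Q/V2, and the
hybrid constants α > β > 0 are the roots of s² − (k10+k12+k21)s + k10·k21.
The central concentration is computed in closed form by superposing, over
all dose events, the during-infusion term (R/V)·Σ(cᵢ/λᵢ)(1 − e^(−λᵢu)) and
its post-infusion decay, where (cᵢ, λᵢ) are the partial-fraction
coefficients of the unit-bolus response. AUC over any window is the exact
antiderivative of the same expression, so no quadrature error enters the
exposure metrics. When the discriminant collapses (α ≈ β, reachable only on
a measure-zero parameter set), the root gap is floored at 10⁻⁹·(α+β); the
induced relative error is of the same order. A stiff-ODE integration of the
mass-balance system serves as an independent oracle in the tests (closed
form agrees to 10⁻⁶ relative).

Units are fixed package-wide: hours, mg, L, mg/L, mg·h/L. Concentrations
represent total polymyxin B (B1 + B2 summed), matching the assay convention.

## Population model

Inter-individual variability is lognormal (P_i = tv_P·e^η, η ~ N(0, ω²)) on
CL, V2 and Q; V carries no random effect in the final model. The lognormal
realization of the "proportional" IIV model is the standard pharmacometric
convention and guarantees positive parameters. Residual error is
proportional with SD 0.24 (CV 24%); the reported residual estimate is not
explicitly labelled as proportional or additive in the source, but 0.24 mg/L
additive would be implausibly small against the 0.2–10 mg/L assay range, so
the proportional reading is the default and an additive variant is
selectable (`residual_model="additive"`). Simulated concentrations below
zero (a < 0.02% event at CV 24%) are truncated at zero. Simulated exposures
(AUCs) use the residual-error-free individual prediction; residual error
applies only to observed concentrations.

## Synthetic cohorts

The raw clinical data are unavailable, so cohorts are generated to match
the published summaries: 26 subjects; TBW from a Beta(2, 38/9) scaled to
[75, 125] kg (median ≈ 90); BMI uniform on [30.04, 40.35]; height
back-computed from TBW and BMI and required to fall in [152.4, 220] cm (the
domain of the ideal-body-weight formula — infeasible TBW/BMI pairs are
redrawn); sex 17:9 male:female; age discrete-uniform 18–83; serum
creatinine and GFR truncated-lognormal around the cohort medians (76 µmol/L,
80.9 mL/min·1.73 m²); SOFA discrete-uniform 5–17. Doses draw uniformly from
loading {100, 150, 200} mg and maintenance {50, 75, 100} mg q12h, infused
over 1 h during data generation. Ten subjects are rich-sampled at 0, 1,
1.5, 2, 4, 6, 8 h after the day-4 morning dose (t = 72 h); sixteen are
sparse-sampled at 0 and 2 h; a per-subject 4–7-sample subsampler is
available since the true per-patient schedules were not published.
Observations below the LLOQ (default 0.25 mg/L, the summed B1 + B2 assay
lower limits) are flagged and excluded from estimation, mirroring the
study's exclusion criterion.

What the generator does **not** emulate: irregular clinical sampling times,
dose adjustments during therapy, assay error structure beyond a constant
CV, correlated covariates (TBW and BMI are drawn independently), or
infection-site/pathogen attributes. Passing recovery tests therefore show
that the estimation machinery is sound under the stated design, not that it
is robust to every feature of real TDM data.

## Estimation

The marginal likelihood is approximated by FOCE with interaction: per
subject, the joint −2 log density is minimized over η (damped Gauss-Newton
with a finite-difference Jacobian, gradient tolerance 10⁻⁶, compiled per
subject when numba is available), and the objective contribution is
ln|V_i| + r_i'V_i⁻¹r_i + n_i·ln 2π with V_i = G_iΩG_i' + Σ(η̂_i) and
r_i = y_i − f_i(η̂_i) + G_iη̂_i. The residual variance is evaluated at the
individual prediction (the interaction term). On one-random-effect toy
problems the OFV agrees with adaptive-quadrature exact marginal −2LL to
well under one unit; with all ω² = 0 it reduces algebraically to the exact
weighted-least-squares −2 log-likelihood.

The outer problem runs L-BFGS-B on log-transformed parameters (log θ, log ω,
log σ; covariate coefficients untransformed) with a two-point numerical
gradient, followed by an optional Nelder-Mead polish. The inner η solver
always restarts from zero so the objective is a pure function of the outer
parameters — a warm-started inner solver leaves order-10⁻⁴ hysteresis that
defeats quasi-Newton line searches. Initial typical values come from a
naive-pooled log-scale least squares of the four structural parameters
(robust on sparse two-point subjects that have no observable terminal
phase, which is why a terminal-slope initializer was not used); ω² start at
0.2 and σ at 0.2.

**Search region.** A steady-state-only sampling window cannot distinguish
elimination from slow distribution into an arbitrarily large peripheral
compartment: the likelihood has a second, non-physiologic basin with CL → 0
and V2 → ∞ whose OFV ties or beats the physiologic one on weakly
informative (especially resampled) cohorts. The optimizer is therefore
boxed to a physiologically defensible region — CL ∈ [1, 50] L/h (polymyxin
B elimination is non-renal and reported clearances are 1.3–3.1 L/h),
V ∈ [1, 300] L, V2 ∈ [1, 300] L, Q ∈ [0.05, 200] L/h — and a fit pinned to
a box face is reported as non-converged. Bootstrap replicates that end on a
face are counted and excluded, the standard handling of boundary runs; with
the 26-subject design roughly a third of replicates end there, which is
itself a faithful signal of how weakly this design identifies the
distribution parameters.

Standard errors come from the central-difference Hessian of the OFV on the
natural scale (cov = 2H⁻¹), with RSE% = 100·SE/estimate and Wald 95% CIs.
η-shrinkage is 1 − SD(EBE)/ω (sample SD); the > 0.5 rule is exposed as a
model-reduction advisory and reproduces the exclusion of the V random
effect under sparse sampling.

Covariate search: continuous covariates enter as power models normalized to
the cohort median, sex as a multiplicative exp(θ·I) shift; each of the 12
candidates (age, TBW, BMI, IBW, ABW, sex, SOFA, three CrCL variants, SCr,
GFR) is tested on CL by default; the parameter each covariate is paired
with is an open design choice, and other pairings are selectable. Forward addition
accepts the best candidate while ΔOFV > 6.63 (p = 0.01, 1 df); backward
elimination removes any effect whose removal raises the OFV by ≤ 10.83
(p = 0.001). Ties within 0.01 OFV resolve alphabetically for determinism.

## Diagnostics

CWRES decorrelate each subject's residuals by the Cholesky factor of the
FOCE-linearized covariance at the conditional mode; a singular covariance
falls back to element-wise weighted residuals with a warning. The pc-VPC
bins observations by nominal time after dose (protocol times by default),
rescales every observed and simulated value by bin-median PRED / own PRED,
and compares observed 5th/50th/95th percentiles (Hazen interpolation —
stated because percentile dialects move band edges) against the 90% band of
the same percentiles across simulation replicates. Single-observation bins
merge into a neighbor.

## Dosing simulation

Exposure simulations draw 1,000 subjects, administer the loading dose at
t = 0 and maintenance q12h from t = 12 h, all infusions at 50 mg/h, and
integrate the individual predicted profile analytically. AUC_ss,24h is the
day-4 window [72, 96) h by default — subjects with large V2 have terminal
half-lives of days and are not at steady state on day 4, and the windowed
integral (not the 2·dose/CL shortcut, which is also provided) is what
reproduces the published toxicity probabilities. AUC₀₋₂₄ is the first-day
integral including the loading dose. Targets: 50 ≤ AUC_ss,24h ≤ 100 mg·h/L
(inclusive), toxicity AUC_ss,24h > 100 (strict; ties are measure-zero), PTA
= P(AUC₀₋₂₄/MIC > 50) over MIC ∈ {0.125, …, 8} mg/L with adequacy at
PTA ≥ 90%. The five fixed regimens follow the methods-text loading doses
(100/150/200/250/300 mg paired with 50/75/100/125/150 mg); the published
table's row labels cap the two high-dose loadings at 200 mg, and that
variant is selectable (`fixed_regimen_set("table_labels")`) — the choice
affects only AUC₀₋₂₄/PTA, not day-4 exposure. Weight-based doses
(2.5 mg/kg loading, 1.25 or 1.5 mg/kg maintenance at the 10th/50th/90th
percentiles of TBW/ABW/IBW) are not rounded to vial sizes. A closed-form
lognormal cross-check, P(50 ≤ D/CL ≤ 100) as a difference of normal CDFs in
ln CL, validates the clearance machinery independently of any integration
convention.

## Problem sizes and numerical choices

Monte Carlo tables use n = 1,000 subjects per regimen (binomial 95% CI
half-width ≈ 3.1 pp near p = 0.5). Estimation checks refit twenty
re-simulated 26-subject cohorts; the bootstrap uses 200 replicates (a
deliberate scale-down from the study's 1,000 that leaves the percentile CI
stable to well under its own width); the pc-VPC defaults to 1,000
replicates with smaller counts used in self-tests. Inner η tolerance is
10⁻⁶ on the gradient (mode error enters the OFV only at second order);
outer ftol 10⁻⁹; SE Hessian steps are 10⁻³ relative. All randomness flows
through explicit `numpy.random.Generator` seeds; cohorts, fits, bootstraps
and simulation tables are bit-reproducible under a fixed seed.

## Known limitations

* FOCE is an approximation: with ω²_V2 = 1.0 and a day-4-only design, V2,
  Q and their variances are weakly identified and their estimates carry
  visible bias even at 100 rich-sampled subjects (the approximate-likelihood
  optimum genuinely sits away from the generating values); V and CL are
  recovered well, and CL — the parameter that drives every exposure
  conclusion — is unbiased to within a few percent.
* BLQ observations are excluded, not likelihood-censored; at the default
  LLOQ this touches ~1% of observations.
* No absorption models, nonlinear elimination, renal-replacement clearance
  terms, off-diagonal Ω, or covariate-dependent typical values (the final
  model has none).
* Structural comparison (one- vs two- vs three-compartment) is supported
  only as repeated fits under user-chosen specs; the package implements one-
  and two-compartment variants via fixed parameters.
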