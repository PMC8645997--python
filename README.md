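# polypk

Population pharmacokinetics of polymyxin B in obese adults: a two-compartment
nonlinear mixed-effects analysis pipeline with Monte Carlo dosing simulation.

Polymyxin B is a last-line antibiotic for multidrug-resistant Gram-negative
infections with a narrow window between efficacy (AUC_ss,24h of 50–100 mg·h/L)
and nephrotoxicity (AUC_ss,24h above 100 mg·h/L). It is labelled for
total-body-weight dosing, which in obese patients (BMI ≥ 30) risks
over-exposure because clearance does not scale proportionally with weight.
This package re-implements, as a reusable and tested pipeline, the analysis
that addresses that question for a 26-patient obese cohort:

* **synthetic cohorts** emulating the study design (TBW 75–125 kg, BMI
  30.04–40.35, loading 100–200 mg + 50–100 mg q12h, day-4 rich 7-point or
  sparse 2-point sampling, LLOQ censoring) — the stand-in for raw clinical
  data that were never deposited;
* a **closed-form two-compartment infusion engine** (superposed
  biexponential infusion terms, exact analytic AUC over arbitrary windows);
* **FOCE estimation with interaction** (conditional-mode Laplacian
  approximation of the marginal likelihood), stepwise covariate search
  (forward ΔOFV > 6.63, backward ΔOFV > 10.83), η-shrinkage, and a
  nonparametric bootstrap;
* **diagnostics**: conditional weighted residuals (CWRES) and a
  prediction-corrected visual predictive check (pc-VPC);
* **Monte Carlo regimen evaluation**: day-4 exposure distributions,
  probabilities of target and toxic AUC, and probability of target
  attainment (PTA, total-drug AUC₀₋₂₄/MIC > 50) over MIC 0.125–8 mg/L for
  five fixed and eighteen weight-based (TBW/ABW/IBW) regimens.

## The model

Central-compartment concentration follows a two-compartment model with
zero-order infusion input, parameterized as V (central volume), V2
(peripheral volume), CL (clearance) and Q (inter-compartmental clearance).
The final population model is

    CL_i = 2.86 · exp(η_CL),  η_CL ~ N(0, 0.17)
    V2_i = 39.70 · exp(η_V2), η_V2 ~ N(0, 1.00)
    Q_i  = 7.36 · exp(η_Q),   η_Q  ~ N(0, 0.43)
    V_i  = 11.24              (no random effect: η-shrinkage > 0.5)
    y_ij = C(t_ij; θ_i) · (1 + ε_ij),  ε_ij ~ N(0, 0.24²)

with no covariates (age, weights, CrCL variants, SCr, SOFA, GFR and sex all
failed the ΔOFV > 6.63 forward-addition test).

## Worked example

```python
import polypk as pk

model = pk.PopulationModel()          # the final published model
exp = pk.simulate_exposures(model, pk.RegimenSpec.fixed(200, 100), n=1000, rng=1)
print(pk.exposure_probabilities(exp)["p_target"],
      pk.exposure_probabilities(exp)["p_toxicity"])
print(pk.pta(exp)[0.5])
```

prints (seed 1):

```
60.1 15.6
99.5
```

i.e. under 200 mg loading + 100 mg q12h, 60.1% of simulated obese subjects
reach the efficacious day-4 exposure window, 15.6% exceed the toxicity
threshold, and PTA at MIC 0.5 mg/L is 99.5% — the regimen is adequate
(PTA ≥ 90%) up to MIC 0.5 but nothing higher.

Fitting a re-simulated cohort:

```python
cohort = pk.generate_cohort(pk.StudyDesign(), model, rng=42)
fit = pk.fit(cohort, settings=pk.FitSettings(compute_se=False))
print(round(fit.theta_hat["CL"], 2))   # 2.9  (generating value 2.86 L/h)
```

The same stages are exposed as a CLI:

```bash
polypk generate --seed 7 --out cohort.csv
polypk fit --data cohort.csv --out params.csv
polypk simulate --regimens all --n 1000 --seed 1 --out regimen_table.csv
```

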