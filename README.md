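# fupk — population pharmacokinetics of infusional fluorouracil and skeletal-muscle-index toxicity models

Fluorouracil (5FU) is dosed by body surface area (BSA), yet its plasma
exposure varies widely between patients, and body composition — in
particular the skeletal muscle index (SMI, the L3 muscle cross-sectional
area divided by height squared, cm²/m²) — has been proposed as a missing
covariate. `fupk` is a self-contained pipeline for analysing this question
on therapeutic-drug-monitoring (TDM) data: steady-state 5FU concentrations
from 24-h infusions, CT-derived muscle indices and CTCAE-graded adverse
events. Because patient-level data of this kind are not public, the package
ships a synthetic-cohort generator that reproduces the covariate structure
of the motivating study population (111 patients, ~395 steady-state
samples), so every stage of the analysis can be exercised and validated
end to end.

It is written for pharmacometricians and biostatisticians: the estimation
layer follows NONMEM conventions (dataset columns, OFV scale, shrinkage
reporting) while exposing a scikit-learn-style estimator API.

## The models

**Population PK.** One-compartment disposition with linear elimination and
zero-order infusion input. At steady state the concentration is
C<sub>ss</sub> = R₀/CL. Individual clearance follows a centered
multiplicative covariate model with log-normal between-subject variability:

```
CL_i = CL_pop · (1 + θ_BSA·(BSA_i − 1.97)) · exp(θ_SMI·(SMI_back,i − 3.78)) · exp(η_i),   η_i ~ N(0, ω²)
```

with a proportional residual error DV = C·(1 + ε), ε ~ N(0, σ²). The volume
of distribution (46.1 L) and its variability (51.1 %CV) are fixed: with
steady-state-only sampling they are not identifiable, and the corresponding
random effect shows 100% shrinkage. Estimation maximises the marginal
likelihood; the subject-level random effect is integrated out by adaptive
Gauss–Hermite quadrature centered at the empirical-Bayes mode (the Laplace
expansion; one node recovers classic Laplace/FOCE-type estimation). The OFV
is −2 log L with the n·log 2π constant omitted, so ΔOFV = 3.84 at one
degree of freedom corresponds to p = 0.05 in the likelihood-ratio test that
drives stepwise covariate modeling (forward α = 0.05, backward α = 0.01).
Model robustness is assessed by a subject-resampling non-parametric
bootstrap and a prediction-corrected visual predictive check (pcVPC).

**Toxicity.** For each adverse event, severity is dichotomised at CTCAE
grade ≥ 2 and modelled by logistic regression on an SMI measure,
P(severe) = 1/(1+e^(−z)), z = β₀ + β₁·SMI. The odds ratio per 1 cm²/m²
increase is exp(β₁); an OR below one is also reported as the percent
reduction 100·(1−OR).

## Worked example

Simulate a 111-subject cohort under the published final-model estimates,
refit it, and run the diagnostics:

```bash
python -c "from fupk.model import final_model, save_model; save_model(final_model(), 'final_model.yaml')"
fupk simulate --n-subjects 111 --seed 42 --out synth.csv --ae-out ae.csv
fupk filter   --data synth.csv --max-days 205 --out kept.csv --report excluded.csv
fupk fit      --data kept.csv --model final_model.yaml --out fit.json --ebe-out ebes.csv
fupk vpc      --data kept.csv --model final_model.yaml --nsim 200 --seed 7 --out vpc.json
fupk tox      --data kept.csv --ae-table ae.csv --ae fatigue --smi smi_psoas --out tox.csv
```

which prints

```
wrote 111 subjects / 382 observations to synth.csv
retained 111/111 subjects; excluded 0 (report: excluded.csv)
OFV 4487.557; wrote fit.json
observed median inside envelope in 6/6 bins
ae_type smi_measure   n  n_events multiplicity_adjustment  odds_ratio  ci_lower  ci_upper  p_value flag
fatigue   smi_psoas 111        39                    none     0.09758  0.031259   0.30461 0.000062
```

`fit.json` then contains the refitted parameters with their relative
standard errors, e.g. CL_pop 225.2 L/h (RSE 2.2%), θ_BSA 0.709,
θ_SMI 0.0533, IIV 19.3 %CV with 17% η-shrinkage and a 21.8% proportional
error — the simulation truth (223 L/h, 0.794, 0.0570, 20.9 %CV, 21.4%)
recovered within sampling error from a single cohort. The toxicity row
says that in this replicate each additional cm²/m² of psoas SMI multiplies
the odds of severe fatigue by 0.098 (simulated truth 0.15, i.e. an 85%
reduction), with a Wald p-value of 6×10⁻⁵. `fupk scm` and
`fupk bootstrap` drive the covariate search and the resampling analysis
from the same files.

The same analyses are available programmatically
(`fupk.PopPKEstimator(...).fit(dataset)`, `fupk.SmiToxicityModel().fit(x, y)`,
`fupk.scm`, `fupk.bootstrap`, `fupk.pc_vpc`, `fupk.run_all_ae`).

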