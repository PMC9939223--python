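# Methods

## Scope and data model

The package analyses steady-state therapeutic-drug-monitoring data of
infusional fluorouracil together with CT-derived skeletal-muscle indices
(SMI) and CTCAE-graded adverse events. Data are held in an
`AnalysisDataset` (subjects, dosing events, concentration observations,
adverse-event records) read from and written to NONMEM-convention CSV
files (`ID, TIME, EVID, MDV, AMT, RATE, DV, SS, CYCLE` plus named covariate
columns; the mapping is overridable). Conventions:

- Time is hours since the start of the current infusion, cycle-local;
  CT-to-sampling offsets are whole calendar days, signed.
- Rows with `MDV=1` contribute dosing/covariates but no observation;
  covariates are constant per subject (first value wins, conflicts warn).
- Observations below the assay's lower limit of quantification
  (86 ng/ml) are excluded with a warning. No other BLQ handling is
  attempted; in the simulated cohorts concentrations this low essentially
  never occur.
- Eligibility: subjects are retained when |CT offset| ≤ 205 days,
  inclusive at the boundary.
- Muscle area from a Hounsfield grid counts pixels in the 35–50 HU
  skeletal-muscle window, inclusive at both ends (the source convention
  is unstated; inclusivity is the package's choice), times the pixel
  area. SMI = area / height². AUC = C_ss × infusion duration.
- Adverse events are dichotomised per subject at maximum recorded CTCAE
  grade ≥ 2. Subjects without a record for the queried event are coded 0
  and flagged `observed=False`: an event never documented is taken as not
  clinically relevant. DICOM handling and CT segmentation are out of
  scope; the grid-level arithmetic is the supported entry point.

## Population PK model

One-compartment disposition, linear elimination, zero-order infusion
input. For observation j of subject i,

f_ij = (R₀/CL_i)·1000 ng/ml at steady state, and
f_ij = (R₀/CL_i)·(1 − e^(−(CL_i/V)·t))·1000 before steady state.

Clearance carries the covariate model
CL_i = CL_pop · Π_k f_k(x_ik) · exp(η_i), η_i ~ N(0, ω²), with
multiplier forms `linear_proportional` (1 + θ·(x−c)), `exponential`
(e^(θ·(x−c))), `power` ((x/c)^θ) and `piecewise_linear` (two slopes hinged
at c, two parameters). Every form is centered at a reference value c (the
study median), so CL_pop remains the clearance of the reference patient. A
multiplier driven non-positive raises an error rather than being clipped.

The shipped final model uses the published estimates: CL_pop 223 L/h, a
linear-proportional BSA effect 0.794 centered at 1.97 m², an exponential
back-muscle-SMI effect 0.0570 centered at 3.78 cm²/m², ω = 20.9 %CV and a
21.4% proportional error. The published equation's rendering was not
machine-readable; the linear-BSA/exponential-SMI reading follows the
stated screening strategy (linear covariates retained for BSA, exponential
relations tested for SMI) and reproduces the documented hand values
(e.g. BSA 2.17 → 258.41 L/h, SMI 4.78 → 236.08 L/h). Both forms remain
selectable per effect. V = 46.1 L and ω_V = 51.1 %CV are fixed: with
steady-state-only observations the likelihood does not depend on them
(asserted by a perturbation test), and η_V is excluded from the inner
problem and reported with 100% shrinkage.

IIV is log-normal; reported %CV values convert via
%CV = 100·√(exp(ω²) − 1). Residual variance is
σ_add² + (σ_prop·f)², evaluated at the individual prediction
("interaction"). The legacy initial-model feature — a subject-level
log-normal multiplier on the total residual SD — is available
(`iiv_on_residual`) but off by default; its exact original parametrisation
is not documented, and the log-normal-multiplier reading is this package's
interpretation.

## Estimation

The marginal likelihood integrates η out per subject. The integral is
approximated by Gauss–Hermite quadrature centered at the conditional mode
η̂_i and scaled by the curvature there — i.e. the Laplace expansion defines
the grid. One node is exactly the classic Laplace approximation
(`method="laplace"`); the default is 11 nodes (`method="agq"`), which
agrees with 64-node quadrature and with direct adaptive integration to
well below 10⁻³ on small fixtures, whereas plain Laplace differs by ~10⁻²
at the study's noise levels. Eleven nodes were chosen as the point where
further nodes change the OFV by less than 10⁻⁶ at negligible cost. The
inner mode search is a vectorised safeguarded Newton iteration with
analytic derivatives in the steady-state case and central finite
differences otherwise. With the residual-IIV multiplier active, the second
random effect is integrated by 21-node prior-scaled Gauss–Hermite outside
the adaptive η_CL integral — adequate at the few observations per subject
this feature targets.

OFV = −2 log L with n·log 2π omitted (the pharmacometric convention; all
ΔOFV comparisons are invariant to it). ω = 0 degenerates to the exact
weighted-least-squares −2LL. Maximisation uses L-BFGS-B on transformed
parameters (log for positive parameters, identity for covariate
coefficients), falling back to Nelder–Mead polishing when line search
fails; default relative OFV tolerance 10⁻⁶, 500 iterations. Positive
parameters whose log drifts below −9 are flagged as boundary estimates
(the additive-error behaviour seen in the source analysis).
Non-convergence flags the result instead of raising.

Fitted results report empirical-Bayes estimates (conditional modes, 0 for
subjects without observations), η-shrinkage 100·(1 − SD(η̂)/ω) and
ε-shrinkage 100·(1 − SD(IWRES)) with sample SDs (ddof = 1), and RSEs from
the inverse finite-difference Hessian of OFV/2 (observed Fisher
information); a singular or indefinite Hessian sets a covariance flag
rather than raising. Note IWRES = (DV − IPRED)/SD_residual is standardised
by construction: under a correct model it is ~N(0,1) at any σ, so
"vanishing residuals" checks are on DV − IPRED.

## Covariate search and bootstrap

Stepwise covariate modeling: forward inclusion repeatedly adds the
candidate with the largest ΔOFV significant at α = 0.05 (χ² with df =
number of new parameters: 1, or 2 for piecewise-linear), then backward
elimination removes retained effects whose removal is not significant at
α = 0.01. Ties break on (ΔOFV, candidate order); inner fit failures skip
the candidate with a warning and are recorded in the trace. Candidate
effects are centered at the observed cohort median. The default candidate
list covers demographics, laboratory values, tumour markers, BSA and the
four SMI measures; names absent from a dataset are skipped.

The non-parametric bootstrap resamples subjects (whole records) with
replacement to the original count, without stratification, refits from the
point estimates, and summarises by median and 2.5/97.5 percentiles;
non-converging replicates are counted and excluded. A covariate effect
whose 95% CI spans zero is flagged unreliable — the criterion that removed
the infusion-time effect in the source analysis.

## Diagnostics

pcVPC: observations are prediction-corrected by
pcY = Y · median(PRED in bin)/PRED with PRED the typical (η = 0)
prediction; the same code path corrects observed and simulated records.
`n_sim` replicate datasets are simulated under the fitted model on the
identical design; per bin, the 5th/50th/95th percentiles of each replicate
form a 2.5–97.5% envelope for the observed percentiles. Binning is on time
after infusion start when it varies; with steady-state-only data all times
are equivalent and binning falls back to PRED quantiles (default 6 bins,
configurable; under-filled bins merge with a neighbour). The
goodness-of-fit table reports DV, PRED, IPRED, IWRES and a
FOCE-linearised CWRES approximation, one row per observation.

## Toxicity models

Severe-AE logistic regressions are maximum-likelihood fits
(Newton/IRLS via statsmodels) with Wald covariance. By default one
univariable model per (adverse event, SMI measure) pair; multivariable
z = β₀ + Σβ_k x_k is supported. The additive error term sometimes written
inside the logit has no role in Bernoulli maximum likelihood and is not
estimated. Complete separation is flagged and the last stable iterate
returned; constant outcomes raise. No multiplicity adjustment is applied,
and the output records that explicitly. Confidence bands for P(x) come
from the delta method on the linear predictor mapped through the inverse
logit, so bands stay inside (0, 1).

## Synthetic cohorts

`generate_cohort` emulates the study population: 111 subjects, 75:36
male:female, and truncated log-normal covariates matched to the published
medians and ranges (BSA 1.97 [1.47–2.85] m², age 64 [35–84] y, SMI psoas
1.48 [0.46–3.78], back 3.78 [0.94–8.41], total-HU 9.58 [4.12–18.82],
total-segmented 50.26 [25.47–92.67] cm²/m², dose 2283 [1441–3641] mg/m²).
Only median and range are published; the log-scale SD maps the range to
±2.5 SD (the extremes of ~111 draws) and draws are truncated to the range.
Height is not tabulated and uses a plausible adult distribution
(1.73 [1.50–2.00] m). The four SMI measures share one latent muscularity
factor (default correlation 0.8, configurable): their joint distribution
is unpublished, but the reported effects trend together across measures,
implying strong positive correlation. BSA is generated independently of
the latent factor and is never recomputed from height/weight (weight is
not reported, and no BSA formula is named).

Dosing is dose-per-BSA × BSA per cycle as 24-h infusions. Cycle counts
follow a distribution with median and mode 2 on 1–5; TDM draws per cycle
are 1 or 2 with mean 1.55. The published per-cycle sampling density is not
stated, but one draw per cycle cannot reconcile a median of 2 cycles with
3.6 samples per patient (395/111); the 1-or-2-draw design reproduces both
the cycle distribution and the observation count (~395). Samples are taken
late in the infusion (default 18 h) and flagged steady-state.

`simulate_concentrations` draws one η per subject, computes the model
prediction and applies proportional (and optional additive) error;
negative simulated concentrations (possible only with additive error) are
set missing with a warning. `simulate_adverse_events` draws Bernoulli
severe-event indicators from logistic truths in an SMI measure and emits
them as grade 2 (severe) or grade 0 records, so the dichotomisation step
recovers the simulated outcome exactly. The default AE truths use the
published effect sizes (OR 0.15/unit psoas SMI for fatigue, 0.52/unit
back SMI for polyneuropathy) with intercepts giving ~30% prevalence at the
median SMI — prevalences are not published; 30% is a realistic severe-AE
rate under 5FU-based regimens. All generators are reproducible from a
seed or a shared `numpy.random.Generator`.

What the synthetic cohorts do *not* emulate: dose adjustments between
cycles, longitudinal SMI change, covariate measurement error, correlation
between BSA and muscularity, concomitant chemotherapy, and DPD-genotype
effects. Passing recovery tests therefore demonstrate correctness of the
estimation machinery under the stated model, not robustness to these
real-data features.

## Validation problem sizes

The test suite validates against independent oracles (direct numerical
integration for the OFV, grid searches for modes, hand-written likelihoods
for the logistic fits) on small fixtures, and calibrates the stochastic
operating characteristics at reduced but informative sizes chosen so each
check completes in minutes on one core: 20 study-scale replicates for
final-model parameter recovery; 200 cohorts of 60 subjects for the
forward-inclusion type-I rate (nominal 5%); 20 cohorts for power of the
published BSA effect; 50 cohorts of 40 subjects × 200 bootstrap replicates
(scaled from the published 1000) for CI coverage; 5 cohorts × 200
simulations for pcVPC self-consistency; and n = 1000 plus 50 × n = 111
replicates for the toxicity effect sizes. `scripts/acceptance.py` re-runs
the recovery experiments at the full study scale.

## Known limitations

- Estimation supports a single PK random effect (η on clearance) plus the
  optional residual-IIV multiplier; covariates act on clearance only, as
  volume is unidentifiable from steady-state data.
- CWRES uses the FOCE linearisation (labelled approximate); npde
  diagnostics are not implemented.
- The bootstrap refits with the point estimates as starting values and a
  single optimizer start; pathological replicates are flagged, not
  restarted globally.
- Percentile bootstrap CIs are first-order accurate: small-cohort coverage
  runs slightly below nominal (≈94% at 40 subjects in the calibration
  test).
- The NONMEM dialect reader covers the rectangular one-dose-per-cycle TDM
  layout used here, not arbitrary NONMEM control streams (ADDL/II,
  compartment codes, EVID 2–4).
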