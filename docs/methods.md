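# Methods

## Scope

`ecupop` reimplements, as a tested pipeline, the population
PK/PD/efficacy analysis of an anti-C5 monoclonal antibody (eculizumab and
its biosimilar SB12) in pooled healthy-volunteer and PNH-patient data.
The real trial datasets are not public, so every analysis here runs on
synthetic trials generated at the published designs with the published
final-model estimates as generative truth.  Passing the test suite
therefore demonstrates that the estimation machinery recovers the
parameters of data that *exactly follow its own assumptions* at the
published designs; it says nothing about model misspecification in real
data (nonlinear elimination at supra-therapeutic concentrations,
assay-specific censoring of PD, dropout, dosing deviations — none of
which are simulated).

## Structural models

**PK.** Two-compartment disposition with zero-order infusion input and
first-order elimination, parameterized as (CL, Vc, Vp, Q) with
micro-constants k10 = CL/Vc, k12 = Q/Vc, k21 = Q/Vp and hybrid rate
constants from the characteristic quadratic.  The concentration is the
exact biexponential infusion solution; multiple doses superpose.  Typical
values carry weight as `theta * (WT/80.9)**exponent` on CL and Vc and a
separate patient Vc.  The infusion duration is 35 min (0.583 h) in both
studies; only the phase-I duration is reported, so the phase-III value is
a configurable default.

**PD.** Terminal complement activity follows the direct inhibitory
sigmoid Emax model `TCA = E0 (1 - Imax C^H / (IC50^H + C^H))` with
separate E0 and Imax for healthy subjects and patients.  The source
publication reports parameter descriptions but not the equation; this is
the canonical form consistent with every reported quantity, and it is the
normative equation of this package.

**Efficacy.** LDH follows the direct stimulatory sigmoid Emax model
`LDH = LL0 + LMAX T^g / (LC50^g + T^g)` in TCA, patients only (same
remark about the equation).

Between-subject variability is exponential (`p_i = TV exp(eta)`), with a
CL–Vc correlation in the PK block and diagonal blocks elsewhere; IIV% is
reported as `100 sqrt(omega^2)`.  Residual error is proportional for all
three endpoints (additive/combined variants are implemented and
selectable).  An individual Imax above 1 is possible for extreme etas;
the simulator redraws such etas (probability ~0 at the 2.65% IIV), the
estimator evaluates the model as written.

## Estimation (FOCE-I)

Each subject's empirical Bayes eta mode `eta_hat` minimizes the exact
conditional -2 log-likelihood

    g_i(eta) = sum_j [ log(2 pi v_ij) + (y_ij - f_ij)^2 / v_ij ]
               + log det(2 pi Omega) + eta' Omega^-1 eta,

with the residual variance `v` evaluated at the eta-conditional
prediction (interaction).  The objective then expands the prediction to
first order about the mode, under which each subject's data vector is
Gaussian with mean `f(eta_hat) - J eta_hat` and covariance
`V_i = J_i Omega J_i' + diag(v_i)`, giving

    OFV = sum_i [ log det(2 pi V_i) + r_i' V_i^-1 r_i ],
    r_i = y_i - f_i(eta_hat) + J_i eta_hat

— the conventional first-order-conditional-with-interaction objective.
On toy problems the OFV agrees with adaptive Gaussian quadrature of the
exact marginal likelihood to well under 0.5 (tested).

Numerical design choices:

* Prediction Jacobians in eta are computed by complex-step
  differentiation (exact to machine precision); complex exponentials are
  assembled from real exp/cos/sin for speed.
* Regular infusion trains (the q2w maintenance schedule) are superposed
  through stable geometric series over precomputed dose-completion
  counts, so evaluation cost scales with the number of trains, not the
  number of infusions; the collapsed form agrees with the dense per-dose
  superposition to machine precision (tested).
* The inner (eta) problem is solved by a vectorized modified Newton
  iteration over all subjects at once: exact Hessians by forward
  differences of the exact gradient, eigenvalue-clipped (saddle-free) for
  positive definiteness, Armijo backtracking, step-norm cap 8, and a
  scale-invariant stop when the Newton decrement falls below
  `1e-10 (1+|g|)` (so near-noise-free data with huge gradients still
  terminate).  Cached Hessians from the previous solve warm-start the
  first steps.
* The outer problem runs L-BFGS-B on transformed parameters (log for
  positive quantities, logit for inhibition fractions, Fisher-z for the
  correlation, identity for covariate exponents) with an explicit
  central-difference gradient (step 1e-5); all 2p perturbed objective
  values are evaluated in a single stacked inner solve whose eta state is
  seeded from the converged unperturbed modes.  The search restarts from
  its own optimum (fresh L-BFGS memory) while the OFV keeps improving,
  finishes with a short derivative-free (Powell) polish that digs through
  the flat curved valleys where gradient methods stall, and keeps the
  best point evaluated anywhere.
* The pipeline starts the PD and efficacy stages from the naive pooled
  curve fit twice — once as-is and once with the sigmoidicity increased
  (1.25x / 1.3x) — and keeps the lower-OFV fit: pooled curve fits
  understate Hill-type exponents (between-subject smearing flattens the
  curve), which can trap the hierarchical fit in a local basin.
* Standard errors come from a central finite-difference Hessian of OFV/2
  on the transformed scale with delta-method back-transformation;
  shrinkage is `100 (1 - SD(EBE)/omega)`; CWRES standardizes by the same
  linearized covariance `V_i`.

**Initial estimates.** Hierarchical sigmoid-Emax likelihoods are
ridge-shaped far from the well: inflated eta variances absorb structural
misfit and gradient methods stall on the ridge.  The PD and efficacy
stages are therefore initialized from a naive pooled curve fit (ordinary
least squares of the structural model through all linked
regressor/observation pairs, `ecupop.inits`), and the pooled PK fit from
the healthy-only backbone fit, mirroring the staged strategy of the
original analysis.  Variance initial values should be chosen on the scale
of the data-generating setting; the defaults (20–50% IIV, 15–30%
residual) suit these endpoints.

**Sequential linking (IPP).** After the PK fit, each subject's
model-predicted concentration at every observation time (from their EBE
etas and covariates) is attached as a fixed regressor (`CIPP`); the PD
fit never re-estimates PK parameters.  The PD fit's individual TCA
predictions (`TCAIPP`) feed the efficacy fit the same way.

## Trial simulator

Designs follow the published schedules exactly: phase I — three equal
arms of 80, one 300 mg/35 min infusion, 18 scheduled PK samples (pre-dose
+ 17 post-dose to 1512 h) and 10 PD samples; phase III — 600 mg at weeks
0–3, 900 mg at week 4 and every second week to week 50 (28 infusions),
trough PK at 17 visits, PD at 13, LDH at 29, sequences of 24/25 patients
crossing over at week 26.  Trough samples are stored 1e-6 h before their
dose so closed-form evaluation is unambiguous; the t = 0 sample stays at
the dose time and is flagged missing by the pre-dose rule.

Weights are truncated log-normal at the published medians and ranges
(82.4 kg in [70, 94.3]; 63 kg in [43, 111]); the log-scale SDs (0.06 and
0.18) were chosen once so the published ranges sit near ±2–3 SD.  Age,
height, sex and race are generated at the published frequencies for
realism but are unused by the final models.  Residual errors are
independent across observations and endpoints; PD is generated from the
same individual's model concentration at the nominal time and LDH from
the model TCA (consistent with the direct-response, IPP-linked
structure).  The unplanned product switch in eight patients is not
simulated: under the null no analysis quantity depends on it.

PK values below the 0.8 ug/mL LLOQ and pre-first-dose PK samples are
flagged missing and excluded from the likelihood (M1); a missing day-1
LDH baseline is imputed from the screening record.  At the full design
the simulated BLQ fraction is ~0.18 against 0.141 reported from the real
data — a soft consistency check only, since the real fraction depends on
features (actual sampling times, real between-subject kinetics) that the
generator does not reproduce.

## Covariate search and similarity testing

Stepwise selection is greedy forward inclusion by LRT at p < 0.05
followed by backward elimination keeping covariates significant at
p < 0.01, chi-square df = number of added thetas (2 for the three-level
treatment grouping, 1 for biosimilar-vs-pooled-originator).  Continuous
candidates use the power form centred on the pooled median (weight uses
the fixed 80.9 kg reference); categorical candidates estimate one typical
value per level.  The GAM pre-screening used as a heuristic in the
original analysis is replaced by exhaustive LRT over the declared
candidate list.  Candidates are tested on eta-carrying parameters; ties
break by list order.

The treatment-similarity test extends the final model with a categorical
treatment covariate on one parameter (subject-level label = first-period
treatment) and refits; since the extended model nests the base and starts
at its optimum, small negative OFV deltas are numerical and are clamped
to "no improvement".  Calibration on null simulations (100 replicates of
a 60-subject phase-I design) keeps the empirical type-I error inside the
binomial band around 5%, and a 1.3-fold injected clearance difference is
detected with power near 1 (tested).

## Model qualification

The pcVPC simulates replicates of the observed design from the fitted
model, rescales observed and simulated values by the bin-median
population prediction over the subject's own population prediction, and
compares observed 5th/50th/95th percentile curves with simulation-based
95% bands.  Bins are the nominal sampling times (actual = nominal in
synthetic data, so binning ambiguity vanishes).  Simulated PK values
below the LLOQ are discarded exactly like observed ones so the
percentiles compare like with like under M1 censoring; bins with fewer
than three observed values are reported without percentiles.  The
bootstrap resamples subjects with replacement, stratified by study (flagged,
stratified by default), refitting each replicate from the original
estimates.

## Problem sizes used in the tests

The default test suite runs the headline recovery at the full published
design (240 + 49 subjects, five seeds) and scales the Monte-Carlo
components down to keep the whole suite inside a practical runtime:
similarity calibration uses 100 null replicates of 60-subject phase-I
trials fit with a reduced outer budget (no restarts or polish, the same
settings for both nested fits so the likelihood-ratio comparison stays
symmetric — the empirical type-I error under these settings is what the
calibration test asserts), the stepwise checks use pooled 36 + 12-subject
trials, the pcVPC self-consistency check uses 60 subjects with 1000
simulation replicates, and bootstrap unit tests use a handful of
replicates on small trials (the analysis-scale bootstrap of 1000
replicates is available through `ecupop.evaluate.bootstrap` and the
`06_model_evaluation.py` driver).

## Known limitations

* The FOCE-I objective is an approximation; on richly sampled designs its
  bias is negligible (quadrature-checked on toys) but it is not exact.
* Sequential IPP linking conditions downstream stages on EBE-based
  regressors.  With trough-only patient PK and plateau-dominated patient
  TCA, the linked TCA at the few transition visits is shrunken toward the
  typical curve, and the efficacy curve-shape parameters (LMAX, LC50,
  LGAM) inherit a substantial errors-in-regressor bias at n = 49 with
  ~80% IIV — fits started at the generative truth move away from it to a
  lower OFV.  The LDH floor LL0 is robust; the shape parameters should be
  read qualitatively, which matches the caution the original analysis
  itself attaches to PD/efficacy parameters estimated from trough-only
  data.
* BLQ handling is M1 (discard); no M3 likelihood contribution, no
  censoring of PD at its assay limits.
* No Michaelis–Menten elimination, absorption models, indirect-response
  models, dropout or immunogenicity effects.
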