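# Methods

## Structural model and closed form

Disposition is a linear mammillary two-compartment model with first-order
elimination from the central compartment and zero-order infusion input.
With micro constants k10 = CL/V1, k12 = Q/V1, k21 = Q/V2, the hybrid rate
constants α > β > 0 solve α+β = k10+k12+k21, α·β = k10·k21, and the central
concentration after one infusion of rate R over duration T is the standard
two-exponential expression (rise `1−e^{−λt}` during infusion, biexponential
washout after).  Multiple doses superpose exactly because the system is
linear; the test suite checks the closed form against adaptive-step ODE
integration to a relative tolerance of 1e−6 on randomized parameter sets,
and superposition to 1e−10.

A one-compartment variant exists solely as the comparator in structural
model selection; three-compartment models are out of scope.

Units are fixed throughout: time h, dose mg, volume L, clearance L/h,
concentration mg/L.

## Parameters

| parameter | default | units | role |
| --- | --- | --- | --- |
| θ_CL | 8.33 | L/h | typical clearance at CLCr 78.2 mL/min |
| θ_V1 | 13.4 | L | central volume |
| θ_Q | 3.75 | L/h | intercompartmental clearance at BUN 6.8 mmol/L |
| θ_V2 | 60.4 | L | peripheral volume |
| θ_CLCr | 0.0046 | per mL/min | linear CLCr slope on CL |
| θ_BUN | 0.112 | per mmol/L | linear BUN slope on Q |
| ω²_CL | 0.0591 | — | IIV variance on CL (CV ≈ 25%) |
| ω²_Q | 1.12 | — | IIV variance on Q (CV ≈ 134%) |
| σ² | 0.591 | mg²/L² | additive residual variance |
| fu | 1.0 | — | fraction unbound used in fT>MIC |

The shipped config records these on the variance scale; a
`variance_scale: sd` switch reads them as standard deviations instead.
The CLCr slope is stored as 0.0046 per mL/min: the alternative reading
0.046 would drive clearance negative for CLCr below 56.5 mL/min, well
inside the plausible sepsis range, and is inconsistent with the slope's
reported precision and bootstrap distribution.  No protein-binding
correction is applied (fu = 1 by default) because none is established for
this analysis; the parameter is configurable.

Covariate effects support linear (`TV·(1+θ(x−ref))`), power
(`TV·(x/ref)^θ`) and categorical (`TV·(1+θ·flag)`) forms.  Linear forms
carry guard conditions — the multiplier must stay positive over the
covariate range — enforced at evaluation time and, during fitting, by box
bounds on the slope derived from the observed covariate range.

## Synthetic cohort generator

The generator emulates a retrospective TDM cohort of adult sepsis
patients:

- Continuous covariates (age, weight, albumin, BUN, SCR, eGFR, CLCr) are
  drawn independently from normal distributions with the cohort's mean/SD,
  truncated to the cohort's observed range.  The asymmetric truncation
  shifts realized means (CLCr: nominal 88.91, realized ≈ 98.4 mL/min);
  this is the literal consequence of mean/SD/range summaries and is kept
  as-is.  No covariate correlations are published, so marginals are
  independent; a Gaussian-copula hook accepts a user correlation matrix.
- Dosing follows the product label: 300–600 mg infused over 1 h, 2–4
  times daily; a regimen mix with weights assigns one regimen per subject.
- Sampling is sparse and trough-weighted: on average 1.5 samples per
  subject, drawn from the last quarter of a dosing interval at or after
  the third dose — matching routine TDM practice.  Explicit sampling
  windows (fractions of the interval) can replace the trough rule for
  design studies.
- Observations are typical-prediction-plus-noise with the residual model;
  negative draws are truncated to zero.  Values below the LLOQ of
  0.3 mg/L are retained in the file but flagged BLQ, and the estimator
  excludes them (M1 convention).

What the generator does **not** emulate: time-varying covariates (renal
function is frozen per subject), within-day dose adjustments, covariate
correlations, assay batch effects, and model misspecification — the
generator realizes exactly the statistical model the estimator assumes.
Passing recovery tests therefore demonstrate estimator correctness under
the assumed model, not robustness to real-world violations of it.

## Estimation

The FO objective linearizes the subject prediction in η around zero with
central finite differences (relative step 1e−4) and accumulates
`ln det C_i + r_i' C_i^{-1} r_i` over subjects, grouped by block size for
vectorized batched linear algebra.  The 2π constant is omitted, as is
conventional for this class of software, so only OFV differences are
meaningful.  For models linear in η the FO objective is the exact marginal
−2 log-likelihood (asserted to 1e−8 against the closed-form normal
density).

Optimization is quasi-Newton (L-BFGS-B) over log-transformed structural
and variance parameters (positivity by construction) and untransformed
covariate slopes with feasibility box bounds; `ftol` is tightened to
1e−12 so refits from a solution are fixed points to ~1e−6 relative.  If
the line search aborts on finite-difference gradient noise, a Nelder–Mead
polish continues from the same point.  Multi-start (default 3, first
start unjittered) guards against local minima; trial fits inside stepwise
selection reuse the parent solution as the single start for speed.
Standard errors come from the inverse numerical Hessian of the OFV
(covariance = 2·H⁻¹), delta-method-transformed back to the natural scale;
RSE% = 100·SE/|estimate|.

Stepwise covariate selection: forward inclusion accepts the candidate
with the largest OFV drop while that drop strictly exceeds 3.84; backward
elimination removes the cheapest covariate while its removal cost does
not strictly exceed 6.63 (a cost of exactly 6.63 is removed).  Equal
deltas break lexicographically on (parameter, covariate), so traces are
deterministic.  Candidate reference values use the cohort median; the
shipped final model hard-codes the reference values 78.2 and 6.8.

Empirical Bayes estimates maximize the joint density of a subject's
observations and η (Nelder–Mead in ≤2 dimensions); IPRED is the
prediction at the mode.  GOF weighted residuals are FO-WRES,
`C^{-1/2}(y − f(0))` under the FO marginal covariance — the consistent
analogue of conditional weighted residuals for an FO fit, and labelled
WRES accordingly.

## Evaluation

Prediction errors are PE = (PRED−DV)/DV·100%, summarized by MDPE
(median), MAPE (median absolute), F20 and F30 (fractions within ±20/30%);
the acceptability standard is |MDPE| ≤ 15%, MAPE ≤ 30%, F20 > 35%,
F30 > 50%.  The non-parametric bootstrap resamples subjects with
replacement to the original cohort size, refits, and reports the median,
5th–95th percentiles and bias% per parameter; failed replicates are
dropped and counted, with a warning above 20%.

The prediction-corrected VPC bins observations by time after last dose
(quantile bins, default 6, sparse bins merged at <5 observations) and
rescales each observed and simulated value by the ratio of the bin-median
typical prediction to its own typical prediction.  Both the 95% band and
the 10th/90th percentile band are reported, since either convention is in
use; the coverage statistic is the fraction of observations inside the
pooled simulated 2.5–97.5% band of their bin.

## Dosing simulation

Virtual patients are drawn covariates-first (truncated-normal sampler),
mapped through the covariate model, then given log-normal IIV on CL and
Q.  Residual error is *not* added — attainment is judged on the true
concentration profile.  Guard-violating covariate draws are resampled and
counted (they cannot occur with the shipped model over the cohort
ranges).

fT>MIC is computed analytically on one dosing interval.  Two interval
conventions are implemented:

- `first_interval` (simulation default): the first dosing interval of
  therapy, before accumulation.  This is the convention under which the
  package's attainment rates line up with published biapenem sepsis
  simulations, and it is the conservative choice clinically — early
  adequate exposure in empirical sepsis therapy is what drives outcome.
- `steady_state`: the accumulation limit, computed exactly by geometric
  summation of each exponential term (ratio e^{−λτ}); this is the
  convention the scalar `ft_above_mic` defaults to.

The scalar path refines threshold crossings by bisection (Brent) to
~1e−9 h, making the result grid-free; the vectorized population path uses
a dense interval grid (≈2,400 points) with linear interpolation at
crossings, agreeing with the scalar oracle well inside 0.1 percentage
points.  PTA surfaces are computed for the regimen grid
{300, 600} mg × {q6h, q8h, q12h} (1-h infusions) over the doubling MIC
series 0.0625–2 mg/L, at the primary 70% and secondary 40% targets, with
subjects processed in chunks of 2,500 to bound memory.  PTA is monotone
non-increasing in MIC and non-decreasing in daily dose; both properties
are asserted in tests on every run.

## Simulation study designs and problem sizes

- PTA reproduction: 10,000 virtual subjects per run (binomial SE ≤ 0.5
  percentage points), full 6-regimen × 6-MIC grid; ~1 minute on one CPU.
- Parameter recovery: 10 cohorts of 300 subjects, all on 600 mg q6h, two
  samples each — one in the distribution phase (0.17–0.30 of the
  interval) and one mid/late (0.35–0.60) — chosen as the smallest
  informative design for the full 9-parameter model.  Trough-only
  designs leave the peripheral parameters weakly identified.
- Covariate selection: 10 cohorts of 200 subjects, a 300 mg q6h / 600 mg
  q12h mix, one early + one trough sample; candidates are CLCr→CL,
  BUN→Q (true effects) and ALB→CL (null).
- Bootstrap and pcVPC tests run at reduced replicate counts; the
  pipeline defaults (1,000 bootstrap replicates, 1,000 VPC simulations)
  match routine practice.

## Known limitations

- **FO bias at large IIV.**  With ω²_Q = 1.12 (CV ≈ 134%) the FO
  linearization is severely strained: in self-recovery simulations the
  typical Q converges toward Q·e^{ω²/2} (≈ 1.7× the generating value) and
  the BUN slope on Q is attenuated by roughly 30–45%, a dilution effect
  of the unexplained variability that persists even when Ω is fixed at
  the generating values.  CL-side parameters (θ_CL, θ_V1, θ_CLCr), with
  their modest ω², recover within a few percent under an informative
  design.  Conditional-estimation methods would remove this bias but are
  deliberately out of scope; users should treat the Q-side estimates of
  an FO fit as descriptive.
- M1 BLQ handling (exclusion) biases clearance upward-censored designs;
  with trough-heavy sampling at 300 mg this contributed a few percent of
  downward bias on θ_CL in recovery experiments.  Likelihood-based BLQ
  treatment (M3) is not implemented.
- The truncated-normal covariate sampler reproduces ranges exactly but
  shifts means (see above); covariate independence is an assumption, not
  a finding.
- No inter-occasion variability, no time-varying covariates, diagonal Ω
  only.
- pcVPC band conventions differ across software; both computed bands are
  exported so plots can follow either.
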