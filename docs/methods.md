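# Methods

## Pharmacokinetic model

Each TDM occasion is modelled as a one-compartment system at steady state
with zero-order infusion (duration `T_inf`) repeated every `τ` hours and
first-order elimination.  Steady state at the first TDM is a modelling
assumption, justified by the sampling-time distribution (median 2.7 days,
several half-lives for all eight drugs).  No accumulation-from-first-dose or
multi-compartment behaviour is modelled, and there is no Bayesian/population
estimation: the elimination rate constant comes solely from the log ratio of
the two elimination-phase concentrations of the occasion.

The infusion phase is the exact steady-state superposition
`C(t) = A·(1 − e^{−ke t}) + Cmin·e^{−ke t}`, with `A` fixed by
`C(T_inf) = Cmax`; the elimination phase decays exponentially from `Cmax`.
Threshold crossings are solved in closed form with logarithms, and the
closed-form time-above-threshold is validated against a dense-grid (0.001 h)
evaluation of the same profile in the test suite (tolerance 0.5 percentage
points over 1,000 random scenarios).

Boundary conventions: the profile is compared to thresholds with strict `>`;
a free trough exactly at the threshold counts as attained (the limit of the
never-crossing case), while a free peak exactly at the threshold does not
(measure-zero contact).  For continuous infusions the plateau is the
arithmetic mean of the random samples and attainment is a step function.

Occasions that cannot support an estimate — trough-only occasions, rising or
flat concentration pairs — are rejected with a diagnostic and flagged in the
attainment report, never silently dropped.  Only one peak/trough pair per
occasion is used (the earliest complete pair, tie-broken by the earliest
peak).  Unbound fractions are fixed per drug; drugs without a configured
binding fraction (amoxicillin, imipenem, nafcillin) raise a configuration
error rather than defaulting.  Units are fixed: hours, mg, L, mg/L.

## MIC resolution

For polymicrobial episodes the highest measured MIC across all isolates of
the episode is used (including serial cultures; the alternative —
per-organism only — is not distinguishable from the available description).
Cefazolin against methicillin-susceptible *S. aureus* uses a fixed 2 mg/L
target that by default overrides a measured value (configurable).
Culture-negative episodes fall back to the breakpoint of the suspected
pathogen from a small editable table shipped as a synthetic default
(`source_tag="synthetic-default-v1"`); it is a stand-in for a laboratory's
CLSI table, not a clinical reference.  Intrinsically resistant organism/drug
pairs are a resolution error: the underlying service excluded resistant
infections.

## Therapy adjustment

An edit is an *increase* when any of daily dose, frequency or infusion
duration strictly rises and none falls (symmetrically for *decrease*).
Mixed-direction edits are undefined under that rule and are resolved by
comparing predicted attainment at the episode's MIC — exposure is the axis
the ordinal coding is meant to capture.  The recommendation search predicts
attainment for every menu candidate via the reconstructed CL and V (linear
kinetics) and returns the least intensive candidate reaching 100%
fT>h×MIC, ranked by daily dose, then administrations per day, then infusion
duration; with no attaining candidate the maximal-attainment one is returned
flagged best-effort.  Dose menus are per-drug fixtures reflecting label
dosing and are configuration, not clinical advice.  Renal dose caps are not
modelled; renal function affects the simulation through clearance instead.
The target multiplier h is an explicit parameter (1–4), reflecting that
clinicians chose targets in that range case by case.

## Synthetic cohort generator

The generator emulates the statistical structure of a 297-episode ICU TDM
service cohort; its defaults are the study conditions, not tuning knobs.

* **Covariates.** Age ~ N(56, 17²) truncated at 18; weight ~ N(82, 32²)
  truncated at 30 kg; 57% male; SOFA ~ round(N(6, 4²)) ≥ 0; baseline
  creatinine ~ N(1.26, 1.14²) truncated at 0.2 mg/dL; RRT 14%.  A single
  shared severity latent variable (loading 0.3) couples SOFA and RRT; no
  other joint structure is asserted.  29 episodes are second infections
  assigned to random patients (shared age/weight/sex; episode-level severity
  redrawn); outcomes are independent across episodes.
* **Infection sources** lung 44%, bacteremia 17%, skin/soft tissue 9%,
  intra-abdominal 7%, urinary 6%, bone/joint 5%, endocarditis 4%, other 8%.
* **Drugs and modes.** Cefepime-dominant mix (45% cefepime, 20% meropenem,
  12% piperacillin, …). 91% intermittent infusions cohort-wide; extended
  (3–4 h) and continuous modes are only available for drugs with a
  long-infusion menu, so their conditional probability is inflated to keep
  the marginal at 91/7/2.
* **PK truth.** `CL = CL_typ · (CrCl/100)^0.75 · e^η` (Cockcroft–Gault CrCl,
  clipped to 5–160 mL/min), replaced by `CL_typ · 0.35 · e^η` under RRT;
  `V = V_typ · (weight/70) · e^{η_V}`; ω_CL = 0.35, ω_V = 0.25.  Typical
  values per drug are literature-plausible fixtures (e.g. cefepime 7.5 L/h,
  20 L).  Applying the renal scaling uniformly (also to mostly hepatically
  cleared drugs) is a simplification.
* **Sampling.** Peak at `T_inf + U(0.75, 1.25)` h, trough `U(0.1, 0.5)` h
  before the next dose, both with multiplicative log-normal noise (CV 10%).
  Occasions whose noisy pair happens to be non-decreasing are redrawn, i.e.
  the generator conditions on a resolvable occasion.
* **Days to first TDM** ~ log-normal with (μ, σ) = (1.024, 0.754), the least
  squares fit to the printed quartiles 1.7 / 2.7 / 4.7 d (the triple is not
  exactly log-normal, so the fitted median is 2.78 d).
* **MIC context.** 27% of episodes are culture-negative and use the
  breakpoint fallback.  Measured MICs sit on a doubling-dilution grid around
  per-organism medians, capped at the susceptible breakpoint (resistant
  infections excluded).
* **Clinician step.** Each episode draws a target multiplier
  (P = 0.55/0.10/0.05/0.30 for 1/2/3/4×MIC).  If the reconstructed profile
  misses the target, the recommendation search is adopted with probability
  0.88; if the target is met and fCmin/MIC > 4, de-escalation to the minimal
  attaining regimen happens with probability 0.62.  These behaviour
  parameters were calibrated once so the default cohort reproduces the
  reported change-group split (≈25% increase / 31% decrease / 43% no change,
  57% changed) and then frozen.
* **Outcomes.** Clinical cure and 30-day mortality are Bernoulli draws from
  logistic models whose coefficients are the natural logs of the target
  adjusted odds ratios (cure: 0.92 per day of TDM delay, 1.17 increase, 1.25
  decrease; mortality: 1.14 per SOFA point, 2.07 RRT, 1.05 per year, 4.82
  intra-abdominal, 0.36 increase, 0.67 decrease — categorical contrasts
  against no change, since the three pairwise contrasts are not consistent
  with a single ordinal slope).  Intercepts (1.3139, −5.1019) were calibrated
  by monotone root finding on a 200,000-episode simulated linear-predictor
  sample so the marginals hit 75% cure and 20% mortality
  (`calibrate_intercepts`).  Mortality is a 30-day binary, not a hazard.
* **Length of stay** is generated for survivors only (the time-to-event
  analysis excludes 30-day deaths), log-normal with σ = 0.80 and group
  median offsets e^{∓0.25} around 22 d so that increase < no change <
  decrease; stays beyond 50 d are censored in the analysis stage.

What the generator does **not** emulate: correlated repeat TDM occasions,
within-patient outcome correlation, assay error structure beyond a constant
CV, below-quantification censoring, drug switches, concomitant
antimicrobials, organism-level MIC tables, and ICU (as opposed to hospital)
length of stay.  Passing recovery tests therefore show that the analysis
stack is unbiased for data with this structure, not that the clinical
findings themselves generalize.

## Statistical stage

Logistic models are fitted by Newton/IRLS to a score tolerance of 1e-8 (max
100 iterations), with Wald standard errors from the observed information and
95% intervals as `exp(β ± 1.96·SE)`, matching the reporting convention
recoverable from printed CIs.  Rank-deficient designs raise an error naming
the collinear columns; separation raises a convergence diagnostic rather
than returning silently divergent estimates.  Episodes (not patients) are the
analysis unit, without clustering correction.  The univariate screen and the
multivariable specifications are fixed (not stepwise): cure on days-to-TDM
plus change group; mortality on SOFA, RRT, age, intra-abdominal source plus
change group; the increase-vs-decrease contrast is derived from the fitted
covariance.  The in-package fit is cross-checked against statsmodels to 1e-6
in the tests.

The survival stage prepares records as `(min(LOS, 50), event = LOS ≤ 50)`
for survivors, uses the product-limit estimator, and the k-sample log-rank
chi-square with the standard aggregated-increment handling of ties.  It is
cross-checked against lifelines, a hand product-limit calculation, and a
permutation oracle (agreement within 0.01 at n ≤ 60).  Two-sided α = 0.05
throughout.

## Problem sizes and determinism

The acceptance pipeline uses one 50,000-episode cohort for parameter
recovery and the timing/LOS medians (the adjusted-OR sampling error at that
size is 2–4% — small against the recovery tolerances), and 200 cohorts of
297 episodes for the marginal calibration means.  Every random draw flows
from a single `numpy.random.default_rng(seed)`; identical seeds give
bit-identical cohorts and byte-identical CSVs.

## Known limitations

Single-compartment, single-occasion kinetics; fixed literature unbound
fractions (ICU protein binding is variable); no toxicity ceiling in the
recommendation search (none is defined for the exposure targets used);
single-realization log-rank p-values on 297-episode cohorts fluctuate widely
(only the group ordering is a stable prediction); the breakpoint table is a
synthetic default, not CLSI.
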