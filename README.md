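# betalactam-tdm

Beta-lactams kill bacteria in a time-dependent way: what matters is the
fraction of the dosing interval during which the **free** (unbound) drug
concentration stays above the pathogen's MIC (*f*T<sub>&gt;MIC</sub>).  In
critically ill patients, augmented or collapsed clearance makes label dosing
unreliable, so ICU services measure beta-lactam plasma concentrations
(therapeutic drug monitoring, TDM), compute target attainment, and adjust the
regimen.  This package implements the full analysis chain of such a service
and the outcome models used to ask whether *when* TDM happens and *how*
therapy is adjusted predict clinical cure, 30-day mortality and hospital
length of stay.

It is written for clinical pharmacometricians and biostatisticians: every
computational step is a library function, the numbered scripts under
`analysis/` are thin narrative drivers, and a synthetic ICU cohort generator
stands in for patient-level data so the whole pipeline is reproducible and
testable end to end.

## What is computed

**PK engine** (`betalactam_tdm.pk`) — steady-state one-compartment kinetics
from routine samples. From a peak drawn after the end of the infusion and a
trough drawn before the next dose:

```
ke   = ln(C_peak / C_trough) / (t_trough − t_peak)        t½ = ln 2 / ke
Cmax = C_peak · e^{ke (t_peak − T_inf)}                   Cmin = C_trough
CL   = Dose (1 − e^{−ke·T_inf}) / [T_inf · Cmax (1 − e^{−ke·τ})]    V = CL/ke
```

Free concentrations are `fu × total` with fixed unbound fractions (e.g. 0.98
meropenem, 0.80 cefepime, 0.10 ceftriaxone).  *f*T<sub>&gt;h×MIC</sub> for
h = 1…5 and *f*C<sub>min</sub>/MIC come from the closed-form steady-state
profile (infusion-phase rise plus exponential decay), with threshold-crossing
times solved by logarithms.  Continuous infusions use the mean of random
plateau samples.

**MIC rules** (`betalactam_tdm.mic`) — the highest measured MIC across an
episode's isolates; a fixed 2 mg/L target for cefazolin against
methicillin-susceptible *S. aureus*; a breakpoint-table fallback for
culture-negative episodes.  Every resolution carries a provenance tag.

**Adjustment** (`betalactam_tdm.adjust`) — codes regimen edits as increase /
no change / decrease (daily dose, frequency, infusion duration), and searches
a per-drug dose menu for the least intensive regimen predicted (via the
reconstructed CL and V) to hold 100% *f*T<sub>&gt;h×MIC</sub>.

**Synthetic cohort** (`betalactam_tdm.cohort`) — 297 episodes from 268
patients by default, with ICU-calibrated covariates, patient-specific PK
truth, noisy forward-simulated samples, a clinician-style adjustment step
that produces the change groups, and outcome models whose true effects are
the odds ratios the analysis is meant to recover.

**Outcome statistics** (`betalactam_tdm.outcomes`) — IRLS logistic regression
with Wald intervals (cure: days-to-TDM + change group; mortality: SOFA, RRT,
age, intra-abdominal source + change group), Kaplan–Meier time-to-discharge
excluding 30-day deaths with censoring at 50 days, and the k-sample log-rank
test.

## Worked example

```
$ python analysis/01_simulate_cohort.py
wrote 297 episodes (268 patients) -> results/cohort
age mean (SD): 55 (15) y; male 54%; RRT 14%
days to first TDM median (IQR): 2.8 (1.7-4.7)
therapy change: increase 30%, no_change 45%, decrease 25%
clinical cure 69%; 30-day mortality 20%; median LOS 21 d (survivors)

$ python analysis/03_outcome_models.py
== clinical_cure (n=297)
                     predictor  adj_or  adj_ci_low  adj_ci_high
                   days_to_tdm    0.92        0.86         0.98
        change_group[decrease]    1.43        0.75         2.72
        change_group[increase]    0.98        0.55         1.75
```

Each day of delay before the first TDM sample multiplies the odds of clinical
cure by 0.92 in this realization — at n = 297 the regimen-change contrasts are
noisy (wide CIs), which is exactly why the recovery checks run at n = 50,000,
where the fitted adjusted ORs line up with the generator's true effects
(days-to-TDM 0.92; SOFA 1.14; age 1.05; increase-vs-no-change mortality
≈ 0.36).  `analysis/02_target_attainment.py` writes the per-occasion
attainment report (median *f*T<sub>&gt;MIC</sub> is 100% for most drugs;
*f*C<sub>min</sub>/MIC ≈ 4 for cefepime) and `analysis/04_time_to_discharge.py`
draws the Kaplan–Meier curves, where patients whose therapy was increased
leave hospital earlier than those whose therapy was decreased.

The same stages are available as a CLI:

```
bltdm simulate --seed 1 --output-dir out
bltdm attain  --episodes out/episodes.csv --samples out/samples.csv --output-dir out
bltdm analyze --episodes out/episodes.csv --output-dir out
bltdm report  --episodes out/episodes.csv --attainment out/attainment.csv
```

## Layout

```
src/betalactam_tdm/   pk, mic, adjust, cohort, outcomes, io, cli
analysis/             01_simulate_cohort ... 04_time_to_discharge
tests/                pytest suite (unit, property and acceptance checks)
scripts/acceptance.py end-to-end reproduction of the headline numbers
docs/methods.md       model assumptions, calibration and limitations
```
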