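# Methods

## Model structure

`bdscreen` implements a deterministic expectation (cohort) model with a
stochastic patient-level counterpart. Four diagnostic states partition
the cohort: correctly diagnosed MDD, recognised BD (RBP), unrecognised
BD (UBP), and MDD mislabelled as BD (MDD-as-BD). The last state only
arises from an unconfirmed positive screen. Transitions are one-way:
misdiagnosed states flow to their correct counterpart at the annual
correction rate and corrected patients are absorbing. No incident UBP
enters after baseline, costs are constant over time, and only direct
costs to the payer are modelled — no QALYs, indirect costs, or
half-cycle correction.

### Event ordering within a year

The within-year convention is load-bearing, because survivors,
misdiagnosis counts and the discounted ledger all depend on it:

1. **Correction at the year start.** A fraction q of UBP moves to RBP and
   a fraction q of MDD-as-BD moves to MDD; correction applies in every
   year including year 1, so the fraction of baseline UBP still
   unrecognised during year t is (1−q)^t.
2. **Cost accrual** for the post-correction state occupancy.
3. **Discounting** at (1+r)^−(t−1): year 1 costs are undiscounted.
4. **Attrition at the year boundary**: every state is scaled by (1−a)
   after years 1…T−1 (T−1 applications in total), so enrolment during
   year t is N₀(1−a)^(t−1). Disenrolled patients stop accruing costs;
   no differential attrition by state.

Under this convention the base case gives N₀(1−a)⁴ = 15,000·0.894⁴ =
9,581.7 survivors, N₀p(1−q)⁵(1−a)⁴ = 680.2 residual misdiagnoses, and a
discounted per-patient cost of $50,935.85 — the three figures the tests
pin down. Alternative orderings (attrition before costs, discounting from
year 1, correction at year end) each break at least one of them.

### Screening cascade

All N₀ patients are screened once at t = 0. Expected confusion counts
are TP = N₀·p·sens, FN = N₀·p·(1−sens), FP = N₀(1−p)(1−spec),
TN = N₀(1−p)·spec; a score equal to the cutoff is a positive call. A
positive screen assigns a BD working label. A fraction π (0.75) of
positives is referred for psychiatric evaluation; the psychiatrist
assigns the **true** diagnosis with probability `psych_accuracy`
(1.0 in the base case — the evaluation is the gold standard). Hence:

- referred TP → RBP, unreferred TP → RBP (the label happens to be right);
- referred FP → MDD, unreferred FP → MDD-as-BD;
- FN → UBP, TN → MDD.

With `psych_accuracy` < 1 the error is applied symmetrically, so a
referred TP can be demoted to UBP; this generalisation is a package
choice — the base case never exercises it. Unreferred false positives
are costed at the UBP rate (`c_mdd_as_bd` defaults to `c_ubp`); the
field is independent so this assumption can be relaxed. One-time costs,
N₀·c_screen + π(TP+FP)·c_eval, are incurred at t = 0 and are not
discounted. The cohort thereafter follows the same yearly dynamics, with
correction routing each misdiagnosed state to its correct one.

Counts are expectations carried as real numbers; rounding to whole
persons and dollars happens exactly once, at report serialisation
(half-up; proportions to 2 decimals).

## Parameters

| parameter | meaning | default | units |
|---|---|---|---|
| plan_size | health-plan membership | 1,000,000 | persons |
| mde_incidence | 1-year incidence of a major depressive episode | 0.03 | /year |
| help_seeking | fraction seeking care | 0.50 | — |
| ubp_prevalence p | unrecognised BD among new MDD diagnoses | 0.16 | — |
| annual_correction q | incorrect → correct diagnosis | 0.15 | /year |
| attrition a | all-cause disenrolment | 0.106 | /year |
| referral_prob π | positive screen → psychiatrist visit | 0.75 | — |
| psych_accuracy | evaluation assigns true diagnosis | 1.0 | — |
| horizon T | follow-up | 5 | years |
| c_mdd / c_rbp / c_ubp | annual direct cost per state | 11,760 / 16,092 / 23,696 | 2021 USD |
| c_mdd_as_bd | cost of MDD mislabelled as BD | = c_ubp | 2021 USD |
| c_screen / c_eval | one-time costs | 15 / 230 | USD |
| discount r | annual discount rate | 0.03 | /year |

The q = 0.15 default corresponds to a median ≈6-year delay to a correct
BD diagnosis absent screening. Historical costs are re-expressed in
2021 dollars with a user-supplied inflation factor (`inflation_adjust`);
no CPI series is bundled, and the three state costs imply slightly
different factors from their source values (≈1.674–1.675), so the 2021
figures are taken as direct inputs rather than derived.

## Synthetic operating-point tables

Screening tests enter the model only through cutoff → (sensitivity,
specificity) tables. The generator emulates such tables with an
equal-variance binormal model: controls ~ N(0,1), cases ~ N(μ,1),
μ = √2·Φ⁻¹(AUC), labels i.i.d. Bernoulli(prevalence). Defaults are the
study conditions: AUC 0.92 (the screening algorithm's reported
discrimination; the questionnaire comparator is emulated at a lower
AUC), prevalence 0.16, n = 10,000 scores, cutoff grid 0.01…0.99 step
0.01.

Raw binormal scores are unbounded, while the published cutoff axis is
the unit interval, so profile construction maps scores to the calibrated
posterior P(case | score) under the generating mixture — a monotone
logistic transform that leaves the ROC curve unchanged. This also makes
the decision-curve convention coherent: the score cutoff is read as a
predicted probability, and each threshold probability selects the
profile row with the nearest cutoff. For a perfectly calibrated score
the model's net benefit weakly dominates treat-all and treat-none at
every threshold, which is the behaviour the synthetic stand-in exhibits
across thresholds 0.1–0.8.

Confidence intervals on the tabulated operating points are percentile
bootstrap over resampled (label, score) pairs (default 95 %); a
degenerate resample without both classes falls back to the point
estimate. The bootstrap stream is a deterministic child of the
population seed, and all randomness flows through explicit integer
seeds.

What the generator does **not** emulate: score distributions of real
instruments (shape, discreteness — a 13-item questionnaire's integer
scores in particular), miscalibration, covariate-dependent accuracy, or
correlation between test errors and prognosis. Tests passing on
synthetic profiles therefore validate the model arithmetic and the
optimisation machinery, not any specific instrument's field performance;
real tables can be supplied as CSV
(`cutoff,sensitivity,specificity[,sens_lo,sens_hi,spec_lo,spec_hi]`).

## Oracles and numerical checks

- **Closed form.** The no-screening per-patient cost has an analytic
  geometric-sum form; the engine matches it to 1e-9 relative over 1,000
  random valid parameter draws.
- **Microsimulation.** A vectorised patient-level simulation draws
  screening result, referral, evaluation accuracy, yearly correction and
  disenrolment as independent Bernoulli events; at n = 200,000 it agrees
  with the deterministic engine within 3 Monte-Carlo standard errors.
- **Conservation.** State counts sum to enrolment in every year to 1e-9
  relative; discounted state-cost buckets sum to total minus one-time
  costs.
- Sweep optimisation is exhaustive over the supplied discrete cutoff
  grid — no interpolation — with ties broken toward the lower cutoff.
  Degenerate inputs (zero positives for PPV, thresholds outside (0,1),
  non-monotone profiles) raise typed errors rather than returning
  silent zeros.

## Known limitations

- The screening-arm headline figures depend on the unrounded operating
  points of the instruments' full tables; recomputed from 2-decimal
  operating points they differ by <1 % in cost and a few persons in
  year-5 misdiagnoses (e.g. $49,528/258 vs the published $49,513/260 at
  sens 0.87, spec 0.81). The same applies to PPV at that point: the
  analytic value 0.466 prints as 0.46 only from unrounded inputs. These
  gaps are inherent to the rounded inputs and are asserted at matching
  tolerances rather than forced.
- One-way sensitivity analysis only; no probabilistic sensitivity
  analysis or tornado ranking.
- The 13-variant plan scales paired unit costs jointly (both named costs
  to 50 %/150 %), sets c_mdd := c_rbp for the "RBP = MDD" variant, and
  lets `c_mdd_as_bd` track `c_ubp` throughout — the reading consistent
  with the reproduced no-screening column.
- Attrition is uniform across states; psychiatric capacity, repeat
  screening, and treatment-effect feedback on costs are out of scope.
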