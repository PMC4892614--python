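# Methods

This note records the modelling choices, parameter conventions and
numerical decisions behind `fuzzystage`, and the known limitations.
Every empirical number quoted here is computed by the test suite or by
`scripts/acceptance.py`.

## Variables and normalisation

Five pre-operative inputs are mapped to ordinal group scales:

| variable | raw form | grouped scale |
| --- | --- | --- |
| primary Gleason pattern | 1–5 | identity (1–5) |
| secondary Gleason pattern | 1–5 | identity (1–5) |
| PSA (ng/mL) | positive real | 1–6: [0, 2.6), [2.6, 4.1), [4.1, 6.1), [6.1, 10), [10, 20), [20, ∞) |
| age (years) | positive real | 1–11: <25 → 1, five-year bins to 70, ≥70 → 11 |
| clinical T | T1a–T4 codes | 1–5: T1a–c → 1, T2a → 2, T2b → 3, T2c → 4, T3a/T3b/T4 → 5 |

The target is the pathological binary stage: pT2x → 1 (organ-confined,
OCD), pT3x/pT4 → 2 (extra-prostatic, ED).  A bare "T2" without
laterality maps to group 2 with a warning.  pT1 codes are rejected:
pathological staging of a prostatectomy specimen starts at pT2.

## Fuzzy c-means

Standard FCM with c = 2 clusters, fuzzifier m = 2, Euclidean distance,
convergence when the objective improves by less than 1e-5 (max 100
iterations).  The membership matrix is initialised from a seeded
uniform draw, row-normalised.  Points coinciding with a centre get a
one-hot membership row.  Clusters are tagged OCD/ED by majority vote of
their maximum-membership members; if both clusters land on the same
class, the most ED-enriched cluster is forced to ED and the least
ED-enriched to OCD so both classes are always represented.  The tests
verify the implementation against an independent brute-force
fixed-point iteration to 1e-6.

## Sugeno FIS and ANFIS training

Each FCM cluster becomes one rule of a first-order
Takagi–Sugeno–Kang system.  Antecedents are Gaussian membership
functions `exp(-(x-c)²/2w²)` per input; the initial centre is the
cluster centre coordinate and the initial width the membership-weighted
standard deviation, floored at 0.1.  Firing strengths use the product
t-norm; the output is the firing-weighted average of the linear rule
consequents.  If all firings underflow to zero the nearest rule (by
premise distance) is used, with a warning.

Hybrid training alternates, per epoch:

1. a **global least-squares solve** of all consequent coefficients
   (design matrix of normalised firings times `[1, x]`), with a small
   ridge fallback (λ = 1e-6) if the system is rank-deficient;
2. a **normalised-gradient descent step** on the premise centres and
   widths, widths clamped at 0.01.

The step size adapts: ×1.1 after four consecutive improvements, ×0.9
when an epoch fails to improve, in which case the epoch is rolled back,
so the recorded RMSE trace is non-increasing.  Training stops at the
epoch budget or an error goal.

### Identifiability

In a two-rule system the output depends on the premises only through
the log-firing-ratio, a quadratic in each input with three coefficients
per input derived from four premise parameters.  Premise parameters are
therefore identifiable only up to a one-dimensional flat direction (for
equal widths, simultaneous equal centre shifts compensated by width
changes).  Consequently:

- recovery of a known system is asserted on **held-out prediction
  RMSE** (≤ 0.1 from 500 samples with noise SD 0.05 within 100
  epochs), which is well-posed;
- direct premise-parameter recovery is only tested for a
  zeroth-order-consequent system with a perturbation chosen orthogonal
  to the flat direction, and then to 5 % relative error after 1500
  epochs.  Components of an initialisation error lying along the flat
  direction are never corrected, by construction of the model class.

## AJCC 2010 nomogram baseline

The anatomic stage groups I–IV are implemented as a first-match rule
table in the published row order over T, N, M, PSA and Gleason sum,
including the rows that apply only when PSA or Gleason are unknown.
The baseline score is the ordinal stage rank (1–5); the binary
reduction maps I/IIA/IIB → OCD and III/IV → ED.  The tests check an
exhaustive truth table with boundary marker values and monotonicity in
each of T, N, M.

## Evaluation

ROC curves sweep all distinct score cutoffs with "score ≥ cutoff ⇒
positive"; AUC is the trapezoid rule, which the tests prove identical
(to 1e-12) to the tie-adjusted Mann–Whitney pair statistic computed in
exact rational arithmetic.  The operating point maximises Youden's J,
ties broken toward the smaller false-positive rate.  Model agreement
with pathology uses McNemar's test on the discordant counts
(uncorrected χ² with 1 df; an exact binomial option exists); b = c
yields p = 1.  Cohorts are split once, 2/3 training (round(n·2/3), i.e.
266/133 at n = 399) and 1/3 validation, shared by every model under
comparison.

## Synthetic cohort generator

Real patient records cannot be shipped.  The generator draws, per
patient, a class (ED prevalence 220/399), then each grouped variable
from a class-conditional distribution obtained by **exponential
tilting** of the published marginal frequency table:
`q_ED ∝ p·exp(δ(1-π)g)` and `q_OCD ∝ p·exp(-δπg)` with π the ED
prevalence, which preserves the marginal to first order.  The tilt δ
per variable is calibrated by root-finding so the ED−OCD conditional
mean gap matches the published values (≈0.16 for each Gleason pattern,
≈0.32 for clinical T group, 0 for PSA and age — the variables reported
non-significant).  Raw values are then drawn uniformly inside the
group's interval, and a pathological T code consistent with the class
is attached.  The generator reproduces marginal frequencies (within
2 % at n = 10 000), conditional means (within 0.05 at n = 50 000) and
is byte-deterministic per seed.

The generator emulates **univariate** structure only: it does not model
correlations between inputs (e.g. Gleason–PSA), so the joint
distribution is simpler than a real cohort and multivariable models
should be expected to perform somewhat differently than published.

## Limitations

- The class signal in the generator is weak by design (it matches the
  published univariate gaps), so validation AUCs hover in the
  0.55–0.70 range and **model orderings vary across seeds**: on the
  default seed-1 cohort the neuro-fuzzy model beats the nomogram (0.651
  vs 0.587), but other seeds can flip that ordering.  Fixed-seed
  results are exactly reproducible; only those are asserted.
- ANFIS minimises squared error against the 1/2-coded target, not AUC;
  training can occasionally reduce validation AUC relative to the
  untrained FCM-seeded system.
- The nomogram baseline assumes N0/M0 when node/metastasis status is
  absent, which matches a clinically localised surgical cohort.
- Bootstrap AUC confidence intervals are percentile intervals over
  patient resampling and inherit the usual small-sample caveats at
  n = 133.
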