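# Methods

## Setting and data model

A spontaneous reporting system (SRS) is a case-only database: each report
describes one patient who experienced at least one adverse event, with the
drugs on board, demographics, and medical history, but with no information
about the population at risk. The package models the four-table layout used
by the Japanese national SRS: DEMO (one row per case: sex, age as a decade
band string), DRUG (one row per drug record: name, involvement category —
suspected / concomitant / interaction — daily dose in mg, start date), REAC
(one row per adverse event: MedDRA preferred term, onset date), and HIST
(one row per medical-history entry). Dates may be complete, year-month,
year-only, or absent; ingest preserves the reported precision
(`PartialDate`) and nothing is imputed. Column headers, delimiters and
encodings are configuration, since real dumps use Japanese headers and
CP932 encoding. All involvement categories are included when selecting the
study drug's reports.

The relational join produces one `CaseRecord` per DEMO id; child rows with
ids absent from DEMO go to an orphan report rather than being dropped, so
row counts are conserved at every stage. Duplicate DEMO ids are rejected —
deduplication of true duplicate reports is out of scope and assumed done
upstream.

## Case definition

The target event is defined by a term set (an SMQ): a case is positive when
any REAC preferred term matches (exact match after case-folding and
trimming), and has a positive history flag when any HIST term matches. When
several target-event rows carry dates, the earliest complete date is taken
as the onset date: time-to-onset needs a single onset per case, and the
earliest is the conservative choice. A partial onset date still makes the
case positive but contributes no usable onset day. The bundled 10-term
demo list is a synthetic stand-in (MedDRA is licensed); the real
narrow-scope convulsions SMQ (code 20000079) has 101 preferred terms and is
supplied by the user as a one-term-per-line text file.

## Cohort construction

Exclusions — unknown sex; unknown or non-numeric age ("child", "adult",
"elderly"); unknown study-drug dose; lithium use with unknown dose — are
applied in that fixed order, attributing each excluded case to the first
failing rule; this makes the flow ledger deterministic and conserves
`n_input = n_retained + Σ exclusions` by construction. Covariate choices
that the analysis pattern leaves open were resolved as follows:

- **Dose bands.** <200 mg low, 200–400 mg medium (closed at both edges, as
  the band labels "<200", "200–400", ">400" force), >400 mg high. Lithium:
  ≤600 mg low, >600 mg high, no-use reference. Edges are configurable.
- **Multiple study-drug rows.** The per-case dose is the maximum
  non-missing dose (peak exposure); `first` and `mean` rules are available.
- **Polypharmacy.** Any drug in the (editable, bundled) antipsychotic list
  other than the study drug itself.
- **Antiepileptics.** The five agents sodium valproate, carbamazepine,
  lamotrigine, clonazepam, diazepam. An agent counts as non-concomitant
  only when the case has a complete seizure onset date and *every* matching
  drug row has a complete start date strictly after it; rows with missing
  or partial start dates count as concomitant (no evidence of starting
  after onset — the conservative reading).

## Reporting odds ratios

The adjusted ROR comes from a multivariable logistic regression of case
status on treatment-coded dummies in a fixed documented order (intercept,
sex, 4 age dummies, 2 dose, polypharmacy, 2 lithium, fluvoxamine,
antiepileptic, history — 14 columns). The sex reference level is male by
default and configurable. The likelihood is maximized by Newton/IRLS
(statsmodels), covariance from the inverse observed information;
rank-deficient designs raise an error naming the collinear columns, and
separation or non-convergence is reported (`converged=False`, a warning,
and a hard error in the pipeline) rather than silently returning estimates.
No Firth or other penalty is applied: the method this package implements is
the ordinary logistic aROR, and separation is a finding about the data, not
something to paper over. Wald intervals and p-values use a fixed critical
value 1.959964 for bit-stable output; profile-likelihood intervals are not
implemented. The crude ROR uses the standard 2×2 formula with the
Haldane–Anscombe 0.5 correction optional for zero cells; an uncorrected
zero-cell table yields a flagged undefined estimate, not an exception.

## Time-to-onset

Onset day = (onset date − earliest complete study-drug start date) + 1, so
same-day onset is day 1 and all days are positive as Weibull support
requires; the alternative `half_day` convention (raw difference, same-day
→ 0.5) is available since published analyses rarely state their
convention. Days beyond the 1,095-day window are excluded and counted;
nonpositive differences (onset before start) are recording errors counted
with the missing-date exclusions. Median and quartiles use numpy's default
inclusive linear interpolation, stated so results are bit-reproducible.

The Weibull fit maximizes the log-likelihood over (log α, log β) with BFGS
(analytic gradient, method-of-moments start: β₀ = (π/√6)/sd(log t)); if the
line search stalls the fit is accepted only when the score is numerically
zero, else polished by Nelder–Mead, else an error. Confidence intervals
are Wald on the log-parameter scale from a central-difference observed
information, back-transformed — they can never cross zero. Requirements:
n ≥ 3 positive days with nonzero spread. Failure classification follows
the shape CI: containing 1 (inclusive) → random, lower limit > 1 →
wear-out, upper limit < 1 → early. The onset histogram uses half-open bins
[0, w), [w, 2w), … spanning the whole window, retaining empty tail bins.

## Synthetic-data generator

`synth.simulate` emits the four tables plus exact ground truth. Covariates
are drawn independently at configured prevalences; case status is Bernoulli
at log-odds computed on the *same* dummy coding the analysis uses, so
estimator checks are free of coding mismatches; onset days are Weibull
draws rounded up to whole days; dates are placed uniformly in the
configured reporting window. Missingness is applied after outcome
generation and is missing-completely-at-random (MCAR) — the complete-case
exclusion cascade is unbiased under MCAR, and that assumption is exactly
what the generator encodes. Default conditions (chosen once):

- planted effects: ln of the published adjusted RORs for dose (3.05
  medium, 9.81 high), polypharmacy (1.68), lithium (1.63 low / 1.66 high),
  fluvoxamine (2.79), antiepileptics (0.49), history (8.49); sex ln 0.9 and
  age effects (−0.7, −0.9, −1.1, −1.2) set qualitatively (all older groups
  report less than the ≤29 reference); intercept −3.0, giving an overall
  seizure fraction near 11% of analyzable study-drug reports;
- onset: α = 193 days, β = 1.0, matching a 134-day exponential median;
- missingness: dose 28%, age 3% missing + 5% non-numeric, sex 2%, lithium
  dose 15% of users, dates 5% missing + 5% partial — reproducing an
  exclusion scale of roughly one third of reports;
- `paperlike_config()` is these conditions with every report a study-drug
  case; `recovery_config()` raises fluvoxamine/history/lithium prevalences
  (0.15/0.10/0.25) for parameter-recovery studies, so every design column
  carries event counts in the regime where Wald intervals are near-nominal
  — at 2% fluvoxamine prevalence a recovery experiment would measure
  small-sample sparsity, not estimator correctness.

What the generator does **not** emulate: reporting dynamics over calendar
time (stimulated reporting, under-reporting), duplicate reports, free-text
dose strings, correlated covariates, or informative missingness. Passing
tests therefore demonstrate correctness of the pipeline's logic and the
calibration of its estimators under clean conditions — not robustness to
the real database's duplicates, MNAR missingness, or coding drift.

## Problem sizes and numerical checks

The test suite checks, among others: exact identity between the pipeline
run on emitted tables and the generator's ground truth (zero-missingness,
1,000 reports); Wald CI coverage of all 13 planted log-odds at 0.95 ± 0.03
over 200 cohorts of n = 2,000; Weibull shape CI coverage over 500 samples
of n = 222 (shape 1.1, scale 180 d); agreement of the Weibull MLE with an
iteratively refined 41×41 grid search to 1e−4 on samples of n ≤ 10; and
equality of exp(logistic slope) with the 2×2 odds ratio to 10 significant
digits on 100 random tables. The qualitative profile check fits the full
model on a 100,000-report paperlike dump.

One measured limitation: rounding onset days up to integers plus the
1,095-day window truncation bias the fitted shape upward by about 2–3% at
β = 1. This is invisible at the scale of a published onset analysis (a few
hundred cases, where the shape CI spans ±10%), but at tens of thousands of
onsets the CI becomes tight enough to exclude 1, so the random-failure
classification is checked — and should be interpreted — at study-scale
sample sizes (n ≈ 222). A truncation-aware likelihood would remove the
bias and is a possible extension.
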